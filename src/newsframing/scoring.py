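"""Cosine-similarity framing scores for victim records against frame vectors."""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import VictimRecord
from .embedding import EmbedderBackend, embed_article, embed_terms
from .lexicon import FrameLexicon


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class FramingScore:
    """Cosine similarity of one victim's text to one frame, in [-1, 1]."""

    victim_id: str
    frame: str
    score: float
    gender: str = "unspecified"
    circumstances: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not -1.0 <= self.score <= 1.0:
            raise ScoringError(
                f"score {self.score} for ({self.victim_id}, {self.frame}) "
                "outside [-1, 1]"
            )


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity u.v / (|u||v|), clamped to [-1, 1].

    Raises on zero vectors or mismatched dimensions; the clamp only absorbs
    floating-point drift, never a genuinely out-of-range value.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ScoringError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ScoringError("cosine undefined for a zero vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def frame_vectors(
    lexicons: Sequence[FrameLexicon], backend: EmbedderBackend
) -> list[tuple[FrameLexicon, np.ndarray]]:
    return [(lex, embed_terms(lex, backend)) for lex in lexicons]


def score_corpus(
    victims: Sequence[VictimRecord],
    frames: Sequence[tuple[FrameLexicon, np.ndarray]],
    backend: EmbedderBackend,
) -> list[FramingScore]:
    """Score every victim against every frame (complete grid, |victims| x |frames|)."""
    if not frames:
        raise ScoringError("no frames to score against")
    if not victims:
        raise ScoringError("no victim records to score")
    scores: list[FramingScore] = []
    for victim in victims:
        if not victim.text.strip():
            raise ScoringError(f"victim {victim.victim_id!r} has empty text")
        article_vec = embed_article(victim.text, backend)
        for lex, frame_vec in frames:
            scores.append(
                FramingScore(
                    victim_id=victim.victim_id,
                    frame=lex.frame,
                    score=cosine(article_vec, frame_vec),
                    gender=victim.gender,
                    circumstances=victim.circumstances,
                )
            )
    return scores


def write_scores(scores: Sequence[FramingScore], path: str | Path) -> None:
    """Scores CSV: victim_id,gender,circumstances,frame,score."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["victim_id", "gender", "circumstances", "frame", "score"])
        for s in scores:
            writer.writerow(
                [s.victim_id, s.gender, ";".join(sorted(s.circumstances)),
                 s.frame, repr(s.score)]
            )


def read_scores(path: str | Path) -> list[FramingScore]:
    out: list[FramingScore] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                FramingScore(
                    victim_id=row["victim_id"],
                    frame=row["frame"],
                    score=float(row["score"]),
                    gender=row["gender"],
                    circumstances=frozenset(
                        c for c in row["circumstances"].split(";") if c
                    ),
                )
            )
    return out
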