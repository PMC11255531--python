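"""Synthetic annotated news corpora with known framing structure.

Articles are token sequences from a synthetic background vocabulary
("tok0042"-style strings, guaranteed disjoint from any real-word frame
lexicon) into which frame-lexicon tokens are injected i.i.d. per token at a
rate that may depend on the decedent's gender, circumstance and the frame.
Because the hash embedding backend maps disjoint vocabularies to
near-orthogonal vectors, the injection rate directly controls how similar an
article's embedding is to a frame's centroid — so every downstream estimator
can be validated against known ground truth without any real data.

The defaults mirror a realistic annotated news sample: 153 cisgender-male
and 64 cisgender-female decedents, circumstance frequencies proportional to
observed per-gender attribution counts, and a stigma-language injection
contrast of 0.15 (male) vs 0.05 (female) with the other frames uninjected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .corpus import Article, VictimAnnotation
from .lexicon import FrameLexicon

GENDER_PAIR = ("cis_male", "cis_female")

#: Observed per-gender circumstance attribution counts in an annotated news
#: sample; normalised to per-gender sampling probabilities.
_MALE_CIRC_COUNTS = {
    "unspecified": 35, "legal_problem": 31, "mental_health": 29,
    "social_relationship": 21, "physical_health": 24, "financial_job": 10,
    "preceding_suicidality": 9,
}
_FEMALE_CIRC_COUNTS = {
    "unspecified": 24, "legal_problem": 9, "mental_health": 8,
    "social_relationship": 13, "physical_health": 8, "financial_job": 9,
    "preceding_suicidality": 4,
}


def _normalise(counts: Mapping[str, int]) -> dict[str, float]:
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic corpus.

    ``injection_rates`` maps ``(gender, circumstance, frame)`` to a per-token
    injection probability; the circumstance slot accepts the wildcard ``"*"``
    (gender-wide rate regardless of circumstance).  For a victim with several
    circumstances the maximum matching rate applies.
    """

    n_victims: Mapping[str, int] = field(
        default_factory=lambda: {"cis_male": 153, "cis_female": 64}
    )
    circumstance_distribution: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "cis_male": _normalise(_MALE_CIRC_COUNTS),
            "cis_female": _normalise(_FEMALE_CIRC_COUNTS),
        }
    )
    injection_rates: Mapping[tuple[str, str, str], float] = field(
        default_factory=lambda: {
            ("cis_male", "*", "stigma"): 0.15,
            ("cis_female", "*", "stigma"): 0.05,
        }
    )
    extra_circumstance_prob: float = 0.08
    background_vocab_size: int = 500
    sentences_per_article: tuple[int, int] = (4, 10)
    tokens_per_sentence: tuple[int, int] = (8, 20)
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_victims.items():
            if n < 1:
                raise SyntheticError(f"n_victims[{g!r}] must be positive")
        for g, dist in self.circumstance_distribution.items():
            if any(not 0 <= p <= 1 for p in dist.values()):
                raise SyntheticError(f"probabilities for {g!r} outside [0,1]")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise SyntheticError(
                    f"circumstance distribution for {g!r} must sum to 1"
                )
        for key, rate in self.injection_rates.items():
            if not 0 <= rate <= 1:
                raise SyntheticError(f"injection rate for {key} outside [0,1]")
        for name, (lo, hi) in (
            ("sentences_per_article", self.sentences_per_article),
            ("tokens_per_sentence", self.tokens_per_sentence),
        ):
            if lo < 1 or hi < lo:
                raise SyntheticError(f"{name} range {lo, hi} is empty")

    def rate(self, gender: str, circumstances: frozenset[str], frame: str) -> float:
        candidates = [
            self.injection_rates.get((gender, c, frame), 0.0) for c in circumstances
        ]
        candidates.append(self.injection_rates.get((gender, "*", frame), 0.0))
        return max(candidates)


@dataclass(frozen=True)
class GroundTruth:
    """Realized injection statistics per (gender, frame)."""

    token_counts: Mapping[tuple[str, str], int]  # (gender, frame) -> injected tokens
    total_tokens: Mapping[str, int]  # gender -> token count
    circumstance_counts: Mapping[str, Mapping[str, int]]  # gender -> circ -> count

    def realized_rate(self, gender: str, frame: str) -> float:
        return self.token_counts.get((gender, frame), 0) / self.total_tokens[gender]

    def to_dict(self) -> dict:
        return {
            "realized_rates": {
                f"{g}/{f}": self.realized_rate(g, f)
                for (g, f) in sorted(self.token_counts)
            },
            "total_tokens": dict(self.total_tokens),
            "circumstance_counts": {
                g: dict(c) for g, c in self.circumstance_counts.items()
            },
        }


def _background_vocab(size: int) -> list[str]:
    return [f"tok{i:04d}" for i in range(size)]


def synthetic_lexicons(n_terms: int = 60) -> list[FrameLexicon]:
    """Synthetic frame lexicons sized like a real expanded attitude lexicon.

    Each frame gets ``n_terms`` synthetic tokens ("stigma007"-style),
    guaranteed disjoint from the background vocabulary and from each other.
    The default of 60 terms per frame emulates a scale of ~20 descriptors
    per dimension after synonym expansion.  Size matters: with a k-term
    frame vocabulary, injected tokens of one frame leak into another frame's
    cosine score in proportion to 1/sqrt(k) of the per-article sampling
    noise, so a degenerately small lexicon (a few tokens) produces spurious
    between-group differences on uninjected frames that a realistically
    sized one does not.
    """
    out = []
    for frame in ("stigma", "glorification", "isolation"):
        terms = tuple(f"{frame}{i:03d}" for i in range(n_terms))
        out.append(
            FrameLexicon(frame=frame, seed_terms=terms[:3], expanded_terms=terms)
        )
    return out


def _check_disjoint(lexicons: Sequence[FrameLexicon], background: Sequence[str]) -> None:
    bg = set(background)
    for lex in lexicons:
        clash = lex.vocabulary & bg
        if clash:
            raise SyntheticError(
                f"frame {lex.frame!r} vocabulary overlaps the background "
                f"vocabulary: {sorted(clash)[:5]} (would confound frames)"
            )


def _article_tokens(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    gender: str,
    circumstances: frozenset[str],
    lexicons: Sequence[FrameLexicon],
    background: Sequence[str],
    counters: dict[tuple[str, str], int] | None = None,
) -> list[str]:
    """One article's sentences as token lists joined with terminal periods."""
    rates = [(lex, spec.rate(gender, circumstances, lex.frame)) for lex in lexicons]
    total_rate = sum(r for _, r in rates)
    if total_rate > 1.0:
        raise SyntheticError(
            f"injection rates for ({gender}, {sorted(circumstances)}) sum to "
            f"{total_rate} > 1"
        )
    n_sent = rng.integers(spec.sentences_per_article[0],
                          spec.sentences_per_article[1] + 1)
    sentences = []
    for _ in range(n_sent):
        n_tok = rng.integers(spec.tokens_per_sentence[0],
                             spec.tokens_per_sentence[1] + 1)
        tokens = []
        for _ in range(n_tok):
            u = rng.random()
            cum = 0.0
            chosen = None
            for lex, r in rates:
                cum += r
                if u < cum:
                    chosen = lex
                    break
            if chosen is not None:
                vocab = sorted(chosen.vocabulary)
                tokens.append(vocab[rng.integers(len(vocab))])
                if counters is not None:
                    counters[(gender, chosen.frame)] = (
                        counters.get((gender, chosen.frame), 0) + 1
                    )
            else:
                tokens.append(background[rng.integers(len(background))])
        sentences.append(" ".join(tokens) + ".")
    return sentences


def _sample_circumstances(
    rng: np.random.Generator, spec: SyntheticSpec, gender: str
) -> frozenset[str]:
    dist = spec.circumstance_distribution[gender]
    names = sorted(dist)
    probs = np.array([dist[c] for c in names])
    first = names[rng.choice(len(names), p=probs)]
    circs = {first}
    if rng.random() < spec.extra_circumstance_prob and len(names) > 1:
        rest = [c for c in names if c != first]
        rest_p = np.array([dist[c] for c in rest])
        rest_p = rest_p / rest_p.sum()
        circs.add(rest[rng.choice(len(rest), p=rest_p)])
    return frozenset(circs)


def generate_corpus(
    spec: SyntheticSpec, frame_lexicons: Sequence[FrameLexicon]
) -> tuple[list[Article], list[VictimAnnotation], GroundTruth]:
    """Generate an annotated single-victim-per-article corpus.

    Deterministic for a fixed spec (including seed).  Returns the articles,
    the victim annotations (no spans: one victim per article), and the
    realized injection ground truth.
    """
    background = _background_vocab(spec.background_vocab_size)
    _check_disjoint(frame_lexicons, background)
    rng = np.random.default_rng(spec.seed)
    articles: list[Article] = []
    annotations: list[VictimAnnotation] = []
    token_counters: dict[tuple[str, str], int] = {}
    total_tokens: dict[str, int] = {}
    circ_counts: dict[str, dict[str, int]] = {}

    idx = 0
    for gender in sorted(spec.n_victims):
        for _ in range(spec.n_victims[gender]):
            idx += 1
            circs = _sample_circumstances(rng, spec, gender)
            sentences = _article_tokens(
                rng, spec, gender, circs, frame_lexicons, background, token_counters
            )
            text = " ".join(sentences)
            aid, vid = f"art{idx:05d}", f"vic{idx:05d}"
            articles.append(Article(article_id=aid, text=text, source="synthetic"))
            annotations.append(
                VictimAnnotation(
                    article_id=aid, victim_id=vid, gender=gender,
                    circumstances=circs,
                )
            )
            n_tok = sum(len(s.split()) for s in sentences)
            total_tokens[gender] = total_tokens.get(gender, 0) + n_tok
            row = circ_counts.setdefault(gender, {})
            for c in circs:
                row[c] = row.get(c, 0) + 1

    return articles, annotations, GroundTruth(
        token_counts=token_counters,
        total_tokens=total_tokens,
        circumstance_counts=circ_counts,
    )


def generate_mixed_gender_articles(
    spec: SyntheticSpec,
    k: int,
    frame_lexicons: Sequence[FrameLexicon] = (),
) -> tuple[list[Article], list[VictimAnnotation]]:
    """Generate k two-victim mixed-gender articles with valid span offsets.

    Each article concatenates a male-victim segment and a female-victim
    segment; the annotations carry disjoint, ordered half-open spans into the
    concatenated text.
    """
    if k < 1:
        raise SyntheticError("k must be >= 1")
    background = _background_vocab(spec.background_vocab_size)
    _check_disjoint(frame_lexicons, background)
    rng = np.random.default_rng(spec.seed + 1)  # distinct stream from generate_corpus
    articles: list[Article] = []
    annotations: list[VictimAnnotation] = []
    for i in range(1, k + 1):
        segments, spans, cursor = [], [], 0
        for gender in GENDER_PAIR:
            circs = _sample_circumstances(rng, spec, gender)
            seg = " ".join(
                _article_tokens(rng, spec, gender, circs, frame_lexicons, background)
            )
            if segments:
                cursor += 1  # the joining space
            spans.append((gender, circs, cursor, cursor + len(seg)))
            cursor += len(seg)
            segments.append(seg)
        text = " ".join(segments)
        aid = f"mix{i:05d}"
        articles.append(Article(article_id=aid, text=text, source="synthetic-mixed"))
        for j, (gender, circs, start, end) in enumerate(spans, start=1):
            annotations.append(
                VictimAnnotation(
                    article_id=aid, victim_id=f"{aid}v{j}", gender=gender,
                    circumstances=circs, span=(start, end),
                )
            )
    return articles, annotations
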