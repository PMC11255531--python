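"""Pluggable text-embedding backends; frame and article vector construction.

A backend maps a non-empty string to a fixed-dimension real vector,
deterministically for a fixed backend version.  Two backends are provided:

* :class:`HashEmbedder` — a download-free deterministic backend in which each
  token hashes to a unit vector and a string embeds as the mean of its token
  vectors.  Tokens with disjoint vocabulary are near-orthogonal in
  expectation, which makes lexicon-injection experiments interpretable and
  every pipeline stage testable offline.
* :class:`TransformerEmbedder` — an optional adapter over a
  sentence-transformers checkpoint (mean pooling), lazily imported.

A *frame vector* is the unweighted mean of the embeddings of a lexicon's
expanded terms.  An *article vector* is the unweighted mean of its sentence
embeddings — the text is split into sentences first, so the representation is
sentence-level rather than a bag of word vectors.
"""

from __future__ import annotations

import hashlib
import re
from typing import Callable, Protocol, Sequence

import numpy as np

from .lexicon import FrameLexicon


class EmbeddingError(ValueError):
    pass


class EmbedderBackend(Protocol):
    name: str
    dimension: int

    def embed_text(self, text: str) -> np.ndarray:
        ...


_TOKEN_RE = re.compile(r"[a-z0-9']+")

#: Common abbreviations that end with a period but do not end a sentence.
_ABBREVIATIONS = {
    "mr", "mrs", "ms", "dr", "prof", "st", "jr", "sr", "vs", "etc", "inc",
    "ltd", "co", "gov", "sen", "rep", "gen", "col", "capt", "lt", "sgt",
    "dept", "univ", "approx", "e.g", "i.e", "u.s", "u.k",
}

_SENT_BOUNDARY = re.compile(r"(?<=[.!?])\s+")


def split_sentences(text: str) -> list[str]:
    """Rule-based sentence splitter on terminal punctuation.

    Splits on whitespace following ``.``, ``!`` or ``?`` unless the token
    before the period is a known abbreviation or a single initial.  Good
    enough for news prose; swap in a different splitter via the ``splitter``
    argument of :func:`embed_article` if needed.
    """
    parts = _SENT_BOUNDARY.split(text.strip())
    sentences: list[str] = []
    buffer = ""
    for part in parts:
        candidate = (buffer + " " + part).strip() if buffer else part
        last_word = candidate.rstrip(".!?").rsplit(None, 1)[-1].lower() if candidate.strip(".!?").strip() else ""
        last_word = last_word.rstrip(".")
        if candidate.endswith(".") and (last_word in _ABBREVIATIONS or len(last_word) == 1):
            buffer = candidate
        else:
            buffer = ""
            if candidate.strip():
                sentences.append(candidate)
    if buffer.strip():
        sentences.append(buffer)
    return sentences


class HashEmbedder:
    """Deterministic hash-based embedding backend.

    Each lowercase token maps, via a BLAKE2 hash keyed by ``seed``, to a unit
    vector of dimension ``dimension`` with i.i.d. Gaussian direction; a
    string's embedding is the mean of its token vectors.  Identical strings
    give bitwise-identical vectors in any process, and tokens never shared
    between two strings give near-orthogonal embeddings in expectation as the
    dimension grows.
    """

    def __init__(self, dimension: int = 256, seed: int = 0):
        if dimension < 2:
            raise EmbeddingError("dimension must be >= 2")
        self.name = f"hash-d{dimension}-s{seed}"
        self.dimension = int(dimension)
        self.seed = int(seed)
        self._cache: dict[str, np.ndarray] = {}

    def _token_vector(self, token: str) -> np.ndarray:
        vec = self._cache.get(token)
        if vec is None:
            digest = hashlib.blake2b(
                token.encode("utf-8"),
                digest_size=8,
                key=str(self.seed).encode("ascii"),
            ).digest()
            rng = np.random.Generator(
                np.random.PCG64(int.from_bytes(digest, "big"))
            )
            raw = rng.standard_normal(self.dimension)
            vec = raw / np.linalg.norm(raw)
            self._cache[token] = vec
        return vec

    def embed_text(self, text: str) -> np.ndarray:
        tokens = _TOKEN_RE.findall(text.lower())
        if not tokens:
            raise EmbeddingError(f"cannot embed text with no tokens: {text!r}")
        return np.mean([self._token_vector(t) for t in tokens], axis=0)


class TransformerEmbedder:  # pragma: no cover - optional heavy dependency
    """Contextual sentence-embedding adapter (optional ``transformer`` extra).

    Wraps a sentence-transformers checkpoint with mean pooling.  Satisfies
    the same backend contract as :class:`HashEmbedder`; the checkpoint name
    is configurable since no single public checkpoint is canonical for this
    task.
    """

    def __init__(self, model_name: str = "all-MiniLM-L6-v2"):
        try:
            from sentence_transformers import SentenceTransformer  # noqa: PLC0415
        except ImportError as exc:
            raise ImportError(
                "TransformerEmbedder requires sentence-transformers "
                "(pip install newsframing[transformer])"
            ) from exc
        self._model = SentenceTransformer(model_name)
        self.name = f"st-{model_name}"
        self.dimension = int(self._model.get_sentence_embedding_dimension())

    def embed_text(self, text: str) -> np.ndarray:
        if not text.strip():
            raise EmbeddingError("cannot embed empty text")
        return np.asarray(self._model.encode(text), dtype=float)


def make_backend(
    backend: str = "hash",
    dimension: int = 256,
    seed: int = 0,
    model_name: str = "all-MiniLM-L6-v2",
) -> EmbedderBackend:
    """Construct a backend from config fields."""
    if backend == "hash":
        return HashEmbedder(dimension=dimension, seed=seed)
    if backend == "transformer":
        return TransformerEmbedder(model_name=model_name)
    raise EmbeddingError(f"unknown backend {backend!r}; expected hash|transformer")


def embed_terms(lexicon: FrameLexicon, backend: EmbedderBackend) -> np.ndarray:
    """Frame vector: unweighted mean of the expanded terms' embeddings."""
    if not lexicon.expanded_terms:
        raise EmbeddingError(f"frame {lexicon.frame!r}: no expanded terms to embed")
    vecs = [backend.embed_text(term) for term in lexicon.expanded_terms]
    out = np.mean(vecs, axis=0)
    if not np.all(np.isfinite(out)):
        raise EmbeddingError(f"frame {lexicon.frame!r}: non-finite frame vector")
    return out


def embed_article(
    text: str,
    backend: EmbedderBackend,
    splitter: Callable[[str], Sequence[str]] = split_sentences,
) -> np.ndarray:
    """Article vector: unweighted mean of per-sentence embeddings."""
    if not text.strip():
        raise EmbeddingError("cannot embed empty article text")
    sentences = [s for s in splitter(text) if s.strip()]
    if not sentences:
        raise EmbeddingError("article text produced zero sentences")
    vecs = [backend.embed_text(s) for s in sentences]
    # canonical summation order: the mean is bitwise-invariant to sentence
    # permutation despite float non-associativity
    vecs.sort(key=lambda v: v.tobytes())
    return np.mean(vecs, axis=0)
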