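"""Frame lexicons: seed terms, synonym expansion, and dual-coder pruning.

Each Stigma of Suicide Scale (SOSS) dimension — stigma, glorification,
isolation — is represented by a small lexicon of attitude words.  Seeds are
expanded with synonyms from a pluggable source (a WordNet adapter when nltk
is available, or a static table shipped with the package), then optionally
pruned by human coder decisions.  Seeds themselves are never pruned.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Protocol, Sequence

logger = logging.getLogger(__name__)

FRAMES = ("stigma", "glorification", "isolation")

PRUNING_POLICIES = ("unanimous_remove", "any_remove")


class LexiconError(ValueError):
    pass


@dataclass(frozen=True)
class FrameLexicon:
    """One frame's vocabulary.

    ``expanded_terms`` is what gets embedded; ``excluded_terms`` records what
    pruning removed.  The two partitions are disjoint and seeds always stay
    in ``expanded_terms``.
    """

    frame: str
    seed_terms: tuple[str, ...]
    expanded_terms: tuple[str, ...]
    excluded_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.seed_terms:
            raise LexiconError(f"frame {self.frame!r}: seed_terms must be non-empty")
        for coll, name in ((self.seed_terms, "seed"), (self.expanded_terms, "expanded"),
                           (self.excluded_terms, "excluded")):
            for t in coll:
                if not t or t != t.lower():
                    raise LexiconError(
                        f"frame {self.frame!r}: {name} term {t!r} must be "
                        "non-empty lowercase"
                    )
        if set(self.expanded_terms) & set(self.excluded_terms):
            raise LexiconError(
                f"frame {self.frame!r}: expanded and excluded terms overlap"
            )
        missing = set(self.seed_terms) - set(self.expanded_terms)
        if missing:
            raise LexiconError(
                f"frame {self.frame!r}: seeds {sorted(missing)} missing from "
                "expanded_terms (seeds are always retained)"
            )

    @property
    def vocabulary(self) -> frozenset[str]:
        """All tokens appearing in expanded terms (phrases split on spaces)."""
        toks: set[str] = set()
        for term in self.expanded_terms:
            toks.update(term.split())
        return frozenset(toks)


#: The three example words the SOSS literature prints per dimension.  The
#: full 80-descriptor instrument belongs to the original scale publication;
#: supply it via CSV for real analyses.
DEFAULT_SEEDS: dict[str, tuple[str, ...]] = {
    "stigma": ("shallow", "pathetic", "immoral"),
    "glorification": ("understandable", "brave", "motivated"),
    "isolation": ("unhappy", "depressed", "sad"),
}


def default_lexicons() -> list[FrameLexicon]:
    return [
        FrameLexicon(frame=f, seed_terms=seeds, expanded_terms=seeds)
        for f, seeds in DEFAULT_SEEDS.items()
    ]


# ---------------------------------------------------------------------------
# Synonym sources
# ---------------------------------------------------------------------------

class SynonymSource(Protocol):
    """Synset lookup: word -> synonym lemmas across noun/verb/adj/adverb."""

    def synonyms(self, word: str) -> set[str]:
        ...


class StaticSynonymSource:
    """Deterministic synonym table (dict- or CSV-backed).

    CSV format: ``word,synonym`` one pair per line, no header required to be
    consumed in order; lookup is case-insensitive.
    """

    def __init__(self, table: Mapping[str, Sequence[str]]):
        self._table = {k.lower(): {s.lower() for s in v} for k, v in table.items()}

    @classmethod
    def from_csv(cls, path: str | Path) -> "StaticSynonymSource":
        table: dict[str, set[str]] = {}
        with open(path, encoding="utf-8", newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].startswith("#") or row[0] == "word":
                    continue
                table.setdefault(row[0].lower(), set()).add(row[1].lower())
        return cls(table)

    def synonyms(self, word: str) -> set[str]:
        return set(self._table.get(word.lower(), set()))


class WordNetSynonymSource:
    """WordNet-backed synonym lookup (requires the optional nltk extra).

    Collects lemma names from all synsets of the word across the noun, verb,
    adjective (incl. satellite) and adverb classes.
    """

    def __init__(self) -> None:
        try:
            from nltk.corpus import wordnet  # noqa: PLC0415
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "WordNetSynonymSource requires nltk (pip install newsframing[wordnet]) "
                "and the wordnet corpus (nltk.download('wordnet'))"
            ) from exc
        self._wn = wordnet

    def synonyms(self, word: str) -> set[str]:  # pragma: no cover - optional
        out: set[str] = set()
        for pos in (self._wn.NOUN, self._wn.VERB, self._wn.ADJ, self._wn.ADV):
            for synset in self._wn.synsets(word, pos=pos):
                for lemma in synset.lemma_names():
                    out.add(lemma.lower())
        out.discard(word.lower())
        return out


# ---------------------------------------------------------------------------
# Expansion and pruning
# ---------------------------------------------------------------------------

def expand_lexicon(seeds: Sequence[str], synonym_source: SynonymSource) -> list[str]:
    """Expand seed words with synonyms.

    Returns the deduplicated union of seeds and their synonyms, lowercased,
    with multiword lemmas normalised from underscore- to space-joined
    phrases.  Order is deterministic: seeds in input order, then the new
    synonyms of each seed lexicographically.  A seed with no synonyms is
    kept as-is with a warning.
    """
    if not seeds:
        raise LexiconError("seeds must be non-empty")
    out: list[str] = []
    seen: set[str] = set()
    for seed in seeds:
        s = seed.lower().strip()
        if s and s not in seen:
            seen.add(s)
            out.append(s)
    for seed in seeds:
        syns = synonym_source.synonyms(seed.lower())
        if not syns:
            logger.warning("expand_lexicon: no synonyms found for seed %r", seed)
            continue
        for syn in sorted(syns):
            norm = syn.lower().replace("_", " ").strip()
            if norm and norm not in seen:
                seen.add(norm)
                out.append(norm)
    return out


@dataclass(frozen=True)
class CoderDecisions:
    """One coder's keep/remove verdicts over the candidate expanded terms."""

    coder_id: str
    decisions: Mapping[str, str]  # term -> "keep" | "remove"

    def __post_init__(self) -> None:
        bad = {t: d for t, d in self.decisions.items() if d not in ("keep", "remove")}
        if bad:
            raise LexiconError(
                f"coder {self.coder_id!r}: decisions must be keep/remove, got {bad}"
            )


def read_coder_decisions(path: str | Path) -> list[CoderDecisions]:
    """Read coder decisions CSV with header ``coder_id,term,decision``."""
    per_coder: dict[str, dict[str, str]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            per_coder.setdefault(row["coder_id"], {})[row["term"].lower()] = (
                row["decision"].lower()
            )
    return [CoderDecisions(cid, dec) for cid, dec in sorted(per_coder.items())]


def apply_pruning(
    frame: str,
    seeds: Sequence[str],
    candidates: Sequence[str],
    decisions: Sequence[CoderDecisions],
    policy: str = "unanimous_remove",
) -> FrameLexicon:
    """Partition candidate terms into an expanded/excluded lexicon.

    A non-seed term is excluded iff coder verdicts satisfy *policy*
    (``unanimous_remove``: every coder says remove; ``any_remove``: at least
    one does).  Seeds are never excluded.  A candidate missing from any
    coder's decisions is an error.
    """
    if not decisions:
        raise LexiconError("apply_pruning requires at least one coder")
    if policy not in PRUNING_POLICIES:
        raise LexiconError(f"unknown policy {policy!r}; expected {PRUNING_POLICIES}")
    seeds_l = [s.lower() for s in seeds]
    seed_set = set(seeds_l)
    expanded: list[str] = []
    excluded: list[str] = []
    for term in candidates:
        t = term.lower()
        if t in seed_set:
            expanded.append(t)
            continue
        verdicts = []
        for coder in decisions:
            if t not in coder.decisions:
                raise LexiconError(
                    f"coder {coder.coder_id!r} has no decision for term {t!r}"
                )
            verdicts.append(coder.decisions[t])
        removed = (
            all(v == "remove" for v in verdicts)
            if policy == "unanimous_remove"
            else any(v == "remove" for v in verdicts)
        )
        (excluded if removed else expanded).append(t)
    for s in seeds_l:  # seeds absent from candidates are still retained
        if s not in expanded:
            expanded.append(s)
    return FrameLexicon(
        frame=frame,
        seed_terms=tuple(seeds_l),
        expanded_terms=tuple(expanded),
        excluded_terms=tuple(excluded),
    )


# ---------------------------------------------------------------------------
# Lexicon CSV I/O (frame,term,role)
# ---------------------------------------------------------------------------

def read_lexicons(path: str | Path) -> list[FrameLexicon]:
    rows: dict[str, dict[str, list[str]]] = {}
    order: list[str] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            frame = row["frame"]
            if frame not in rows:
                rows[frame] = {"seed": [], "expanded": [], "excluded": []}
                order.append(frame)
            role = row["role"]
            if role not in rows[frame]:
                raise LexiconError(f"{path}: unknown role {role!r}")
            rows[frame][role].append(row["term"].lower())
    lexicons = []
    for frame in order:
        r = rows[frame]
        expanded = list(r["seed"])
        expanded += [t for t in r["expanded"] if t not in expanded]
        lexicons.append(
            FrameLexicon(
                frame=frame,
                seed_terms=tuple(r["seed"]),
                expanded_terms=tuple(expanded),
                excluded_terms=tuple(r["excluded"]),
            )
        )
    return lexicons


def write_lexicons(lexicons: Sequence[FrameLexicon], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "term", "role"])
        for lex in lexicons:
            seed_set = set(lex.seed_terms)
            for t in lex.seed_terms:
                writer.writerow([lex.frame, t, "seed"])
            for t in lex.expanded_terms:
                if t not in seed_set:
                    writer.writerow([lex.frame, t, "expanded"])
            for t in lex.excluded_terms:
                writer.writerow([lex.frame, t, "excluded"])
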