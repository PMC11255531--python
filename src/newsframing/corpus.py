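"""Article and annotation I/O, inclusion/exclusion filtering, victim resolution.

The unit of analysis downstream is the *victim*, not the article: an article
reporting several same-gender deaths is collapsed into one record carrying the
full text, while a mixed-gender article is split into per-victim records, each
restricted to an annotated character span.

Spans are 0-based, half-open character offsets into ``Article.text``
(``text[start:end]``), validated on load.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

logger = logging.getLogger(__name__)

GENDERS = ("cis_male", "cis_female", "trans_male", "trans_female", "unspecified")

#: The seven most frequent circumstance codes; the scheme is user-extensible,
#: so these are defaults rather than a closed vocabulary.
TOP_CIRCUMSTANCES = (
    "unspecified",
    "legal_problem",
    "mental_health",
    "social_relationship",
    "physical_health",
    "financial_job",
    "preceding_suicidality",
)

EXCLUSION_REASONS = (
    "homicide_suicide",
    "bombing",
    "attempt",
    "euphemism",
    "fiction",
    "other",
)

#: Reason label used in exclusion reports for articles that match no include
#: keyword at all (distinct from pattern-based exclusions).
NO_KEYWORD = "no_keyword"


class CorpusError(ValueError):
    """Raised on malformed corpus/annotation input."""


@dataclass(frozen=True)
class Article:
    article_id: str
    text: str
    source: str = ""
    date: str | None = None

    def __post_init__(self) -> None:
        if not self.article_id:
            raise CorpusError("article_id must be non-empty")
        if not self.text.strip():
            raise CorpusError(f"article {self.article_id!r}: text is empty")


@dataclass(frozen=True)
class ExcludeRule:
    reason: str
    patterns: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.reason not in EXCLUSION_REASONS:
            raise CorpusError(
                f"unknown exclusion reason {self.reason!r}; "
                f"expected one of {EXCLUSION_REASONS}"
            )
        if not self.patterns or any(not p for p in self.patterns):
            raise CorpusError(f"rule {self.reason!r}: every pattern must be non-empty")


@dataclass(frozen=True)
class FilterRuleSet:
    """Keyword inclusion plus ordered, labelled exclusion rules.

    An article is retained iff its lowercased text contains at least one
    include keyword (word-boundary match) and matches no exclude pattern.
    """

    include_keywords: tuple[str, ...]
    exclude_rules: tuple[ExcludeRule, ...] = ()

    def __post_init__(self) -> None:
        if not self.include_keywords:
            raise CorpusError("include_keywords must be non-empty")
        reasons = [r.reason for r in self.exclude_rules]
        if len(reasons) != len(set(reasons)):
            raise CorpusError("exclusion reason labels must be unique")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterRuleSet":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping) -> "FilterRuleSet":
        include = tuple(str(k).lower() for k in data.get("include_keywords", []))
        rules = tuple(
            ExcludeRule(
                reason=str(r["reason"]),
                patterns=tuple(str(p).lower() for p in r.get("patterns", [])),
            )
            for r in data.get("exclude_rules", [])
        )
        return cls(include_keywords=include, exclude_rules=rules)


#: Small default rule set for tests and demos.  Expert-curated suicide
#: keyword inventories are external material and are not reconstructed
#: here; users supply their own list via YAML for real corpora.
DEFAULT_RULES = FilterRuleSet(
    include_keywords=("suicide", "suicidal", "killed himself", "killed herself",
                      "took his own life", "took her own life"),
    exclude_rules=(
        ExcludeRule("homicide_suicide", ("homicide-suicide", "murder-suicide")),
        ExcludeRule("bombing", ("suicide bombing", "suicide bomber", "suicide attack")),
        ExcludeRule("attempt", ("suicide attempt", "attempted suicide", "survived")),
        ExcludeRule("euphemism", ("political suicide", "career suicide", "suicide squeeze")),
        ExcludeRule("fiction", ("the film", "the movie", "the novel", "fictional")),
    ),
)


@dataclass(frozen=True)
class VictimAnnotation:
    article_id: str
    victim_id: str
    gender: str
    circumstances: frozenset[str]
    span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise CorpusError(
                f"victim {self.victim_id!r}: unknown gender {self.gender!r}"
            )
        if not self.circumstances:
            raise CorpusError(
                f"victim {self.victim_id!r}: circumstances must be non-empty "
                "(use 'unspecified' when none is reported)"
            )
        if self.span is not None:
            start, end = self.span
            if not (0 <= start < end):
                raise CorpusError(
                    f"victim {self.victim_id!r}: invalid span {self.span} "
                    "(need 0 <= start < end)"
                )


@dataclass(frozen=True)
class VictimRecord:
    victim_id: str
    gender: str
    circumstances: frozenset[str]
    text: str

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise CorpusError(f"victim {self.victim_id!r}: text is empty")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_corpus(path: str | Path) -> list[Article]:
    """Read a JSONL corpus (one article object per line).

    Each line must be a JSON object with at least ``article_id`` and ``text``;
    ``source`` and ``date`` are optional.  Blank lines are skipped.
    """
    articles: list[Article] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}:{lineno}: malformed JSON ({exc})") from exc
            if not isinstance(obj, dict) or "article_id" not in obj or "text" not in obj:
                raise CorpusError(
                    f"{path}:{lineno}: object must have 'article_id' and 'text'"
                )
            aid = str(obj["article_id"])
            if aid in seen:
                raise CorpusError(f"{path}:{lineno}: duplicate article_id {aid!r}")
            seen.add(aid)
            articles.append(
                Article(
                    article_id=aid,
                    text=str(obj["text"]),
                    source=str(obj.get("source", "")),
                    date=obj.get("date"),
                )
            )
    if not articles:
        logger.warning("read_corpus(%s): empty corpus", path)
    logger.info("read_corpus(%s): %d articles", path, len(articles))
    return articles


def write_corpus(articles: Iterable[Article], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a in articles:
            fh.write(
                json.dumps(
                    {"article_id": a.article_id, "text": a.text,
                     "source": a.source, "date": a.date},
                    sort_keys=True,
                )
                + "\n"
            )


def read_annotations(path: str | Path) -> list[VictimAnnotation]:
    """Read victim annotations from CSV.

    Header: ``article_id,victim_id,gender,circumstances,span_start,span_end``;
    circumstances are semicolon-delimited; span cells may be empty.
    """
    out: list[VictimAnnotation] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"article_id", "victim_id", "gender", "circumstances"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise CorpusError(
                f"{path}: annotation CSV must have columns {sorted(required)}"
            )
        for row in reader:
            span = None
            s, e = row.get("span_start", ""), row.get("span_end", "")
            if s not in ("", None) or e not in ("", None):
                if s in ("", None) or e in ("", None):
                    raise CorpusError(
                        f"{path}: victim {row['victim_id']!r}: span_start and "
                        "span_end must be given together"
                    )
                span = (int(s), int(e))
            out.append(
                VictimAnnotation(
                    article_id=row["article_id"],
                    victim_id=row["victim_id"],
                    gender=row["gender"],
                    circumstances=frozenset(
                        c.strip() for c in row["circumstances"].split(";") if c.strip()
                    ),
                    span=span,
                )
            )
    return out


def write_annotations(annotations: Iterable[VictimAnnotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["article_id", "victim_id", "gender", "circumstances",
             "span_start", "span_end"]
        )
        for ann in annotations:
            start, end = ann.span if ann.span is not None else ("", "")
            writer.writerow(
                [ann.article_id, ann.victim_id, ann.gender,
                 ";".join(sorted(ann.circumstances)), start, end]
            )


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _boundary_pattern(phrases: Sequence[str]) -> re.Pattern:
    alts = "|".join(re.escape(p) for p in phrases)
    return re.compile(rf"\b(?:{alts})\b")


def filter_corpus(
    articles: Sequence[Article], rules: FilterRuleSet = DEFAULT_RULES
) -> tuple[list[Article], dict[str, int]]:
    """Apply keyword inclusion and labelled exclusion rules.

    Returns ``(included, exclusion_report)``.  Each excluded article is
    counted once, under the first matching rule in rule order; articles with
    no include keyword are counted under :data:`NO_KEYWORD`.  The counts and
    the included set always partition the input.
    """
    include_re = _boundary_pattern(rules.include_keywords)
    rule_res = [(r.reason, _boundary_pattern(r.patterns)) for r in rules.exclude_rules]

    included: list[Article] = []
    report: dict[str, int] = {}
    for art in articles:
        low = art.text.lower()
        if not include_re.search(low):
            report[NO_KEYWORD] = report.get(NO_KEYWORD, 0) + 1
            continue
        for reason, rx in rule_res:
            if rx.search(low):
                report[reason] = report.get(reason, 0) + 1
                break
        else:
            included.append(art)
    logger.info(
        "filter_corpus: %d in, %d included, %d excluded",
        len(articles), len(included), sum(report.values()),
    )
    return included, report


# ---------------------------------------------------------------------------
# Victim resolution
# ---------------------------------------------------------------------------

def resolve_victims(
    article: Article, annotations: Sequence[VictimAnnotation]
) -> list[VictimRecord]:
    """Collapse an article's annotations into victim-level records.

    All annotations sharing one gender collapse into a single record with the
    union of circumstances and the whole article text (several same-gender
    deaths in one report are treated as one).  Mixed-gender annotations yield
    one record per annotation, each *requiring* a span whose slice becomes the
    record's text.
    """
    if not annotations:
        return []
    for ann in annotations:
        if ann.article_id != article.article_id:
            raise CorpusError(
                f"annotation for victim {ann.victim_id!r} references article "
                f"{ann.article_id!r}, not {article.article_id!r}"
            )
    genders = {ann.gender for ann in annotations}
    if len(genders) == 1:
        circs: frozenset[str] = frozenset().union(*(a.circumstances for a in annotations))
        return [
            VictimRecord(
                victim_id=annotations[0].victim_id,
                gender=annotations[0].gender,
                circumstances=circs,
                text=article.text,
            )
        ]
    records = []
    for ann in annotations:
        if ann.span is None:
            raise CorpusError(
                f"article {article.article_id!r} mentions victims of different "
                f"genders; annotation for victim {ann.victim_id!r} needs a "
                "span_start/span_end giving the victim-relevant text"
            )
        start, end = ann.span
        if end > len(article.text):
            raise CorpusError(
                f"victim {ann.victim_id!r}: span {ann.span} exceeds article "
                f"length {len(article.text)}"
            )
        records.append(
            VictimRecord(
                victim_id=ann.victim_id,
                gender=ann.gender,
                circumstances=ann.circumstances,
                text=article.text[start:end],
            )
        )
    return records


def resolve_corpus(
    articles: Sequence[Article], annotations: Sequence[VictimAnnotation]
) -> list[VictimRecord]:
    """Resolve every annotated article in a corpus; unannotated articles are
    skipped, annotations for absent articles are dropped with a warning."""
    by_article: dict[str, list[VictimAnnotation]] = {}
    for ann in annotations:
        by_article.setdefault(ann.article_id, []).append(ann)
    known = {a.article_id for a in articles}
    for aid in sorted(set(by_article) - known):
        logger.warning(
            "annotations reference article %r absent from the (filtered) corpus; "
            "dropped", aid,
        )
    records: list[VictimRecord] = []
    for art in articles:
        if art.article_id in by_article:
            records.extend(resolve_victims(art, by_article[art.article_id]))
    return records
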