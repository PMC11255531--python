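"""Statistical layer: rank tests, mutual information, agreement, count tables.

Conventions used throughout:

* Mann-Whitney U is computed from midranks (so ties are handled); the
  two-sided p-value is exact when both samples are tie-free and
  ``n_a * n_b <= 400``, otherwise a normal approximation with tie and
  continuity corrections is used.
* Mutual information I(G;S) between the binary group label G and the binned
  score S uses the plug-in estimator over shared equal-width bins spanning
  the pooled sample range, reported in bits.  Zero joint cells contribute
  nothing (0 log 0 = 0).  I(G;S) is 0 iff the binned score distribution is
  identical across groups and is bounded by 1 bit for two groups; LARGER
  values mean MORE divergent gender-conditional distributions.
* Percentages are rounded half-up to one decimal.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .corpus import TOP_CIRCUMSTANCES
from .scoring import FramingScore

logger = logging.getLogger(__name__)

EXACT_PRODUCT_LIMIT = 400  # n_a*n_b threshold for exact Mann-Whitney p


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    frame: str
    group_labels: tuple[str, str]
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    U: float
    p: float
    method: str = ""


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    frame: str = "",
    group_labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Two-sided Mann-Whitney U test for a location difference.

    ``U`` is the statistic for the first sample, computed by rank-sum with
    midranks: U_a = R_a - n_a(n_a+1)/2 where R_a is the sum of sample a's
    midranks in the pooled ordering.  Satisfies 0 <= U <= n_a*n_b.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatsError("mann_whitney requires non-empty groups")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks for ties
    u_a = float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2)

    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and a.size * b.size <= EXACT_PRODUCT_LIMIT:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    assert math.isclose(float(res.statistic), u_a, abs_tol=1e-9)
    return GroupComparison(
        frame=frame,
        group_labels=group_labels,
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        U=u_a,
        p=float(min(res.pvalue, 1.0)),
        method=method,
    )


def compare_by_gender(
    scores: Sequence[FramingScore],
    frames: Sequence[str],
    pair: tuple[str, str] = ("cis_male", "cis_female"),
) -> list[GroupComparison]:
    """Per-frame Mann-Whitney comparison of scores between two gender groups.

    Victims of other gender identities are excluded from the test (they are
    typically too few to compare) but remain in the score table.
    """
    out = []
    for frame in frames:
        a = [s.score for s in scores if s.frame == frame and s.gender == pair[0]]
        b = [s.score for s in scores if s.frame == frame and s.gender == pair[1]]
        if not a or not b:
            raise StatsError(
                f"frame {frame!r}: no scores for group "
                f"{pair[0] if not a else pair[1]!r}"
            )
        out.append(mann_whitney(a, b, frame=frame, group_labels=pair))
    return out


# ---------------------------------------------------------------------------
# Mutual information
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MIResult:
    circumstance: str
    frame: str
    mi: float  # bits
    n_a: int
    n_b: int
    binning: str


def _bin_edges(pooled: np.ndarray, bins: int | str) -> np.ndarray:
    lo, hi = float(pooled.min()), float(pooled.max())
    if isinstance(bins, str):
        if bins != "fd":
            raise StatsError(f"unknown binning spec {bins!r}; expected int or 'fd'")
        edges = np.histogram_bin_edges(pooled, bins="fd")
        if edges.size < 3:  # fd collapsed to one bin; keep >= 2 bins
            edges = np.linspace(lo, hi, 3)
        return edges
    if bins < 2:
        raise StatsError("need at least 2 bins")
    return np.linspace(lo, hi, bins + 1)


def mi_between_groups(
    a: Sequence[float],
    b: Sequence[float],
    bins: int | str = 10,
    circumstance: str = "",
    frame: str = "",
) -> MIResult:
    """Plug-in mutual information I(G;S) in bits between group membership G
    and the binned pooled score S.

    Both samples are pooled; shared equal-width bins span the pooled range
    (``bins`` may be an int or ``'fd'`` for Freedman-Diaconis); the joint
    distribution of (G, bin) with empirical cell frequencies gives
    I(G;S) = sum p(g,s) log2[ p(g,s) / (p(g) p(s)) ] over non-zero cells.
    Constant pooled scores carry no information: mi = 0 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatsError("mi_between_groups requires non-empty groups")
    pooled = np.concatenate([a, b])
    if float(pooled.min()) == float(pooled.max()):
        logger.warning("mi_between_groups: constant pooled scores; MI = 0")
        return MIResult(circumstance, frame, 0.0, int(a.size), int(b.size),
                        "degenerate(constant)")
    edges = _bin_edges(pooled, bins)
    counts_a, _ = np.histogram(a, bins=edges)
    counts_b, _ = np.histogram(b, bins=edges)
    joint = np.vstack([counts_a, counts_b]).astype(float)
    mi = mutual_information_bits(joint)
    return MIResult(
        circumstance=circumstance,
        frame=frame,
        mi=mi,
        n_a=int(a.size),
        n_b=int(b.size),
        binning=f"equal_width[{len(edges) - 1}]",
    )


def mutual_information_bits(joint_counts: np.ndarray) -> float:
    """Plug-in MI in bits from a contingency table of counts."""
    joint = np.asarray(joint_counts, dtype=float)
    n = joint.sum()
    if n <= 0:
        raise StatsError("empty contingency table")
    p = joint / n
    p_row = p.sum(axis=1, keepdims=True)
    p_col = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (p_row * p_col))
    mi = float(np.nansum(terms))
    return max(mi, 0.0)  # clip -0.0 / rounding drift


@dataclass
class StratifiedMIMatrix:
    """Circumstance x frame table of between-gender MI scores."""

    cells: dict[tuple[str, str], MIResult | None]
    circumstances: tuple[str, ...]
    frames: tuple[str, ...]
    genders: tuple[str, str]

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            frame: [
                (self.cells[(c, frame)].mi if self.cells[(c, frame)] else np.nan)
                for c in self.circumstances
            ]
            for frame in self.frames
        }
        return pd.DataFrame(data, index=list(self.circumstances))

    def write_csv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "circumstance"
        df.to_csv(path)


def stratified_mi(
    scores: Sequence[FramingScore],
    frames: Sequence[str],
    circumstances: Sequence[str] = TOP_CIRCUMSTANCES,
    bins: int | str = 10,
    genders: tuple[str, str] = ("cis_male", "cis_female"),
) -> StratifiedMIMatrix:
    """Between-gender MI per (circumstance, frame) cell.

    A victim annotated with several circumstances contributes to every
    matching cell.  A cell whose gender split leaves either group empty is
    marked unavailable (None) rather than raising.
    """
    cells: dict[tuple[str, str], MIResult | None] = {}
    for circ in circumstances:
        for frame in frames:
            a = [s.score for s in scores
                 if s.frame == frame and circ in s.circumstances
                 and s.gender == genders[0]]
            b = [s.score for s in scores
                 if s.frame == frame and circ in s.circumstances
                 and s.gender == genders[1]]
            if not a or not b:
                logger.warning(
                    "stratified_mi: cell (%s, %s) has an empty gender group; "
                    "marked unavailable", circ, frame,
                )
                cells[(circ, frame)] = None
                continue
            cells[(circ, frame)] = mi_between_groups(
                a, b, bins=bins, circumstance=circ, frame=frame
            )
    return StratifiedMIMatrix(
        cells=cells,
        circumstances=tuple(circumstances),
        frames=tuple(frames),
        genders=genders,
    )


# ---------------------------------------------------------------------------
# Cohen kappa
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KappaResult:
    labels: tuple
    p_o: float
    p_e: float
    kappa: float


def cohen_kappa(labels_1: Sequence, labels_2: Sequence) -> KappaResult:
    """Chance-corrected agreement between two coders' categorical labels.

    kappa = (p_o - p_e) / (1 - p_e) with p_e from the product of the coders'
    marginal label frequencies.  When both coders are constant and identical
    (p_e = 1, perfect agreement) kappa is defined as 1.
    """
    if len(labels_1) != len(labels_2):
        raise StatsError(
            f"label sequences differ in length: {len(labels_1)} vs {len(labels_2)}"
        )
    n = len(labels_1)
    if n == 0:
        raise StatsError("cohen_kappa requires at least one item")
    alphabet = sorted(set(labels_1) | set(labels_2), key=repr)
    p_o = sum(x == y for x, y in zip(labels_1, labels_2)) / n
    p_e = sum(
        (sum(x == lab for x in labels_1) / n) * (sum(y == lab for y in labels_2) / n)
        for lab in alphabet
    )
    if p_e >= 1.0:
        kappa = 1.0 if p_o == 1.0 else 0.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaResult(labels=tuple(alphabet), p_o=p_o, p_e=p_e, kappa=kappa)


# ---------------------------------------------------------------------------
# Circumstance count table
# ---------------------------------------------------------------------------

def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal round-half-up (so 17.35 -> 17.4, unlike banker's rounding)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CircumstanceTable:
    """Per-gender circumstance attribution counts with one-decimal percentages.

    A victim with k circumstances contributes k counts; the row total is the
    sum over the listed circumstances, so percentages in a row sum to ~100.
    """

    circumstances: tuple[str, ...]
    counts: Mapping[str, Mapping[str, int]]  # gender -> circumstance -> count
    totals: Mapping[str, int]  # gender -> row total

    def percentage(self, gender: str, circumstance: str) -> float:
        total = self.totals[gender]
        if total == 0:
            return 0.0
        return round_half_up(100.0 * self.counts[gender][circumstance] / total)

    def to_dataframe(self) -> pd.DataFrame:
        rows = {}
        for gender in self.counts:
            row = {}
            for c in self.circumstances:
                n = self.counts[gender][c]
                row[c] = f"{n} ({self.percentage(gender, c):g})"
            row["total"] = self.totals[gender]
            rows[gender] = row
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "gender"
        return df

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)


def circumstance_table(
    annotated,
    circumstances: Sequence[str] = TOP_CIRCUMSTANCES,
) -> CircumstanceTable:
    """Build the gender x circumstance attribution table.

    ``annotated`` is any sequence of objects with ``gender`` and
    ``circumstances`` attributes (annotations or victim records).
    """
    if not annotated:
        raise StatsError("circumstance_table requires at least one annotation")
    counts: dict[str, dict[str, int]] = {}
    for item in annotated:
        row = counts.setdefault(item.gender, {c: 0 for c in circumstances})
        for c in item.circumstances:
            if c in row:
                row[c] += 1
    totals = {g: sum(row.values()) for g, row in counts.items()}
    return CircumstanceTable(
        circumstances=tuple(circumstances), counts=counts, totals=totals
    )
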