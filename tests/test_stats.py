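import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata
from sklearn.metrics import cohen_kappa_score, mutual_info_score

from newsframing.scoring import FramingScore
from newsframing.stats import (
    StatsError,
    circumstance_table,
    cohen_kappa,
    mann_whitney,
    mi_between_groups,
    mutual_information_bits,
    round_half_up,
    stratified_mi,
)


# ---------------------------------------------------------------------------
# Mann-Whitney: exhaustive-permutation oracle
# ---------------------------------------------------------------------------

def mw_permutation_oracle(a, b):
    """Two-sided exact p by enumerating every assignment of the pooled
    values to the two groups (no ties assumed)."""
    pooled = list(a) + list(b)
    n, m = len(a), len(b)
    ranks = rankdata(pooled)

    def u_of(idx):
        return sum(ranks[i] for i in idx) - n * (n + 1) / 2

    obs = u_of(range(n))
    lo, hi = min(obs, n * m - obs), max(obs, n * m - obs)
    if lo == hi:
        return 1.0
    total = extreme = 0
    for idx in combinations(range(n + m), n):
        u = u_of(idx)
        total += 1
        if u <= lo or u >= hi:
            extreme += 1
    return min(extreme / total, 1.0)


class TestMannWhitney:
    def test_small_fixture_u_and_exact_p(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.U == 0.0
        assert res.p == pytest.approx(2 / 6, abs=1e-12)
        assert res.method == "exact"

    def test_identical_samples_midrank_u(self):
        a = [1.0, 2.0, 3.0]
        res = mann_whitney(a, a)
        assert res.U == pytest.approx(len(a) ** 2 / 2)

    def test_u_bounds_and_symmetry(self):
        rng = np.random.default_rng(5)
        a, b = rng.standard_normal(6), rng.standard_normal(9)
        res_ab, res_ba = mann_whitney(a, b), mann_whitney(b, a)
        assert 0 <= res_ab.U <= res_ab.n_a * res_ab.n_b
        assert res_ab.U + res_ba.U == res_ab.n_a * res_ab.n_b
        assert res_ab.p == pytest.approx(res_ba.p, abs=1e-12)

    def test_agrees_with_permutation_oracle_4x4(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            a, b = rng.standard_normal(4), rng.standard_normal(4)
            assert mann_whitney(a, b).p == pytest.approx(
                mw_permutation_oracle(a, b), abs=1e-12
            )

    @pytest.mark.parametrize("n_a,n_b", [
        (1, 1), (1, 3), (2, 2), (2, 4), (3, 3), (3, 5), (4, 4), (2, 6), (1, 7),
    ])
    def test_agrees_with_permutation_oracle_all_small_sizes(self, n_a, n_b):
        rng = np.random.default_rng(n_a * 10 + n_b)
        for _ in range(3):
            a, b = rng.standard_normal(n_a), rng.standard_normal(n_b)
            assert mann_whitney(a, b).p == pytest.approx(
                mw_permutation_oracle(a, b), abs=1e-12
            )

    def test_large_or_tied_samples_use_asymptotic(self):
        rng = np.random.default_rng(3)
        res = mann_whitney(rng.standard_normal(25), rng.standard_normal(25))
        assert res.method == "asymptotic"
        res_tied = mann_whitney([1, 2, 2, 3], [2, 3, 4, 4])
        assert res_tied.method == "asymptotic"
        assert 0 <= res_tied.p <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(StatsError):
            mann_whitney([], [1.0])


# ---------------------------------------------------------------------------
# Mutual information
# ---------------------------------------------------------------------------

class TestMutualInformation:
    def test_identical_samples_zero(self):
        a = [0.1, 0.4, 0.4, 0.9]
        assert mi_between_groups(a, a, bins=10).mi == pytest.approx(0.0, abs=1e-12)

    def test_fully_separated_equal_groups_one_bit(self):
        a = np.linspace(0.0, 0.3, 10)
        b = np.linspace(0.7, 1.0, 10)
        assert mi_between_groups(a, b, bins=2).mi == pytest.approx(1.0, abs=1e-12)

    def test_hand_summed_contingency_fixture(self):
        # joint counts [[2,1,0],[0,1,2]]: marginals .5/.5 rows, 1/3 cols;
        # only the 1/3 cells contribute log2(2) each -> MI = 2/3 bits
        joint = np.array([[2, 1, 0], [0, 1, 2]])
        assert mutual_information_bits(joint) == pytest.approx(2 / 3, abs=1e-12)

    def test_matches_sklearn_on_binned_data(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0.0, 1.0, 80)
        b = rng.normal(0.7, 1.0, 60)
        res = mi_between_groups(a, b, bins=6)
        pooled = np.concatenate([a, b])
        edges = np.linspace(pooled.min(), pooled.max(), 7)
        binned = np.clip(np.digitize(pooled, edges) - 1, 0, 5)
        labels = np.r_[np.zeros(80), np.ones(60)]
        expected = mutual_info_score(labels, binned) / math.log(2)
        assert res.mi == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 40), rng.normal(1, 1, 40)
        base = mi_between_groups(a, b, bins=8).mi
        scaled = mi_between_groups(3.0 * a + 5.0, 3.0 * b + 5.0, bins=8).mi
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_constant_pooled_scores_give_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            res = mi_between_groups([0.5, 0.5], [0.5, 0.5, 0.5], bins=10)
        assert res.mi == 0.0
        assert "constant" in caplog.text

    def test_freedman_diaconis_binning(self):
        rng = np.random.default_rng(10)
        res = mi_between_groups(rng.normal(0, 1, 100), rng.normal(0, 1, 100),
                                bins="fd")
        assert res.mi >= 0.0
        assert res.binning.startswith("equal_width[")

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.lists(st.floats(-1, 1, allow_nan=False), min_size=1, max_size=30),
        b=st.lists(st.floats(-1, 1, allow_nan=False), min_size=1, max_size=30),
    )
    def test_bounds_zero_to_one_bit(self, a, b):
        mi = mi_between_groups(a, b, bins=5).mi
        assert 0.0 <= mi <= 1.0 + 1e-12


class TestStratifiedMI:
    @staticmethod
    def make_scores():
        scores = []
        rng = np.random.default_rng(4)
        for i in range(30):
            for gender in ("cis_male", "cis_female"):
                circ = ["legal_problem", "financial_job"][i % 2]
                scores.append(FramingScore(
                    victim_id=f"{gender}{i}", frame="stigma",
                    score=float(rng.uniform(-0.5, 0.5)), gender=gender,
                    circumstances=frozenset([circ]),
                ))
        return scores

    def test_complete_grid_on_complete_corpus(self):
        matrix = stratified_mi(
            self.make_scores(), frames=["stigma"],
            circumstances=["legal_problem", "financial_job"], bins=4,
        )
        assert all(cell is not None for cell in matrix.cells.values())
        assert matrix.to_dataframe().shape == (2, 1)

    def test_multi_circumstance_victim_in_both_cells(self):
        scores = self.make_scores()
        scores.append(FramingScore(
            victim_id="multi", frame="stigma", score=0.1, gender="cis_male",
            circumstances=frozenset(["legal_problem", "financial_job"]),
        ))
        base = stratified_mi(self.make_scores(), ["stigma"],
                             ["legal_problem", "financial_job"], bins=4)
        grown = stratified_mi(scores, ["stigma"],
                              ["legal_problem", "financial_job"], bins=4)
        for circ in ("legal_problem", "financial_job"):
            assert grown.cells[(circ, "stigma")].n_a == (
                base.cells[(circ, "stigma")].n_a + 1
            )

    def test_empty_gender_cell_marked_unavailable(self, caplog):
        scores = [s for s in self.make_scores() if not (
            s.gender == "cis_female" and "legal_problem" in s.circumstances
        )]
        with caplog.at_level("WARNING"):
            matrix = stratified_mi(scores, ["stigma"],
                                   ["legal_problem", "financial_job"], bins=4)
        assert matrix.cells[("legal_problem", "stigma")] is None
        assert matrix.cells[("financial_job", "stigma")] is not None
        assert np.isnan(matrix.to_dataframe().loc["legal_problem", "stigma"])


# ---------------------------------------------------------------------------
# Cohen kappa
# ---------------------------------------------------------------------------

class TestCohenKappa:
    def test_perfect_agreement(self):
        res = cohen_kappa(["x", "y", "x", "z"], ["x", "y", "x", "z"])
        assert res.kappa == 1.0 and res.p_o == 1.0

    def test_hand_computed_2x2_fixture(self):
        # confusion counts (20, 5, 10, 15): p_o = 35/50 = 0.7,
        # p_e = 0.6*0.5 + 0.4*0.5 = 0.5, kappa = 0.2/0.5 = 0.4
        l1 = ["a"] * 25 + ["b"] * 25
        l2 = ["a"] * 20 + ["b"] * 5 + ["a"] * 10 + ["b"] * 15
        res = cohen_kappa(l1, l2)
        assert res.p_o == pytest.approx(0.7, abs=1e-12)
        assert res.p_e == pytest.approx(0.5, abs=1e-12)
        assert res.kappa == pytest.approx(0.4, abs=1e-12)

    def test_independent_random_labels_near_zero(self):
        rng = np.random.default_rng(12)
        l1 = rng.integers(0, 2, 10_000)
        l2 = rng.integers(0, 2, 10_000)
        assert abs(cohen_kappa(l1.tolist(), l2.tolist()).kappa) < 0.05

    def test_matches_sklearn(self):
        rng = np.random.default_rng(13)
        l1 = rng.integers(0, 4, 200).tolist()
        l2 = [(x if rng.random() < 0.7 else int(rng.integers(0, 4))) for x in l1]
        assert cohen_kappa(l1, l2).kappa == pytest.approx(
            cohen_kappa_score(l1, l2), abs=1e-12
        )

    def test_both_coders_constant_and_identical(self):
        assert cohen_kappa(["a", "a"], ["a", "a"]).kappa == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(StatsError):
            cohen_kappa(["a"], ["a", "b"])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.sampled_from("abc"), st.sampled_from("abc")),
                    min_size=1, max_size=40))
    def test_symmetric_in_arguments(self, pairs):
        l1, l2 = [p[0] for p in pairs], [p[1] for p in pairs]
        assert cohen_kappa(l1, l2).kappa == pytest.approx(
            cohen_kappa(l2, l1).kappa, abs=1e-12
        )


# ---------------------------------------------------------------------------
# Circumstance table
# ---------------------------------------------------------------------------

class _Annotated:
    def __init__(self, gender, circumstances):
        self.gender = gender
        self.circumstances = frozenset(circumstances)


OBSERVED_COUNTS = {
    "cis_male": {
        "unspecified": 35, "legal_problem": 31, "mental_health": 29,
        "social_relationship": 21, "physical_health": 24,
        "financial_job": 10, "preceding_suicidality": 9,
    },
    "cis_female": {
        "unspecified": 24, "legal_problem": 9, "mental_health": 8,
        "social_relationship": 13, "physical_health": 8,
        "financial_job": 9, "preceding_suicidality": 4,
    },
}

EXPECTED_PCT = {
    "cis_male": {
        "unspecified": 22.0, "legal_problem": 19.5, "mental_health": 18.2,
        "social_relationship": 13.2, "physical_health": 15.1,
        "financial_job": 6.3, "preceding_suicidality": 5.7,
    },
    "cis_female": {
        "unspecified": 32.0, "legal_problem": 12.0, "mental_health": 10.7,
        "social_relationship": 17.3, "physical_health": 10.7,
        "financial_job": 12.0, "preceding_suicidality": 5.3,
    },
}


def attribution_fixture():
    items = []
    for gender, row in OBSERVED_COUNTS.items():
        for circ, n in row.items():
            items.extend(_Annotated(gender, [circ]) for _ in range(n))
    return items


class TestCircumstanceTable:
    def test_row_totals(self):
        table = circumstance_table(attribution_fixture())
        assert table.totals["cis_male"] == 159
        assert table.totals["cis_female"] == 75

    @pytest.mark.parametrize("gender", ["cis_male", "cis_female"])
    def test_every_percentage_cell(self, gender):
        table = circumstance_table(attribution_fixture())
        for circ, expected in EXPECTED_PCT[gender].items():
            assert table.percentage(gender, circ) == expected, (gender, circ)

    def test_multi_circumstance_victim_counts_each(self):
        table = circumstance_table(
            [_Annotated("cis_male", ["legal_problem", "financial_job"])]
        )
        assert table.counts["cis_male"]["legal_problem"] == 1
        assert table.counts["cis_male"]["financial_job"] == 1
        assert table.totals["cis_male"] == 2

    def test_single_victim_single_circumstance(self):
        table = circumstance_table([_Annotated("cis_female", ["legal_problem"])])
        assert table.percentage("cis_female", "legal_problem") == 100.0

    def test_empty_input_rejected(self):
        with pytest.raises(StatsError):
            circumstance_table([])


class TestRounding:
    def test_half_up_not_bankers(self):
        assert round_half_up(17.35) == 17.4
        assert round_half_up(17.45) == 17.5
        assert round_half_up(2.5, 0) == 3.0
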