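"""Tissue rule, grouping, and the cohort statistics with independent oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

from ctcflow.cohort import (
    assign_group,
    categorical_association,
    concordance,
    group_emt_summary,
    holm_adjust,
    km_estimate,
    kruskal_wallis,
    logrank_test,
    pairwise_rank_test,
    round_half_up,
    spearman_rho,
    tissue_her2_status,
)
from ctcflow.errors import (
    MissingFISHError,
    UnclassifiableError,
    UndefinedStatisticError,
    ValidationError,
)


class TestTissueRule:
    @pytest.mark.parametrize(
        "ihc,fish,expected",
        [
            ("0", None, "negative"),
            ("1+", None, "negative"),
            ("3+", None, "positive"),
            ("2+", 2.5, "positive"),
            ("2+", 1.5, "negative"),
            ("2+", 2.0, "negative"),  # strict > 2.0
        ],
    )
    def test_decision_rule(self, ihc, fish, expected):
        assert tissue_her2_status(ihc, fish) == expected

    def test_equivocal_without_fish_rejected(self):
        with pytest.raises(MissingFISHError):
            tissue_her2_status("2+")

    def test_fish_with_nonequivocal_score_warns_and_ignores(self):
        with pytest.warns(UserWarning, match="ignored"):
            assert tissue_her2_status("3+", 1.0) == "positive"

    def test_printed_score_distribution_yields_13_positive(self):
        """10 IHC 3+, 11 IHC 2+ (3 FISH-positive), 6 IHC 0/1+ -> 13."""
        calls = (
            [tissue_her2_status("3+")] * 10
            + [tissue_her2_status("2+", 2.5)] * 3
            + [tissue_her2_status("2+", 1.5)] * 8
            + [tissue_her2_status("0")] * 3
            + [tissue_her2_status("1+")] * 3
        )
        assert calls.count("positive") == 13
        assert calls.count("negative") == 14


class TestAssignGroup:
    def test_tissue_positive_without_ctc_is_a_not_aprime(self):
        assert assign_group("positive", None) == ("A", False)

    def test_tissue_positive_with_ctc_is_aprime(self):
        assert assign_group("positive", "negative") == ("A", True)

    def test_b_and_c(self):
        assert assign_group("negative", "positive") == ("B", False)
        assert assign_group("negative", "negative") == ("C", False)

    def test_tissue_negative_without_ctc_unclassifiable(self):
        with pytest.raises(UnclassifiableError):
            assign_group("negative", None)

    def test_partition_on_fixture(self, table2):
        sizes = table2["group"].value_counts()
        assert sizes.sum() == 23
        assert (sizes["A"], sizes["B"], sizes["C"]) == (9, 8, 6)
        assert int(table2["a_prime"].sum()) == 9


class TestConcordance:
    def test_fixture_gives_13_of_23(self, table2):
        c = concordance(table2)
        assert (c.n_concordant, c.n_total, c.percent) == (13, 23, 57)

    def test_all_agreeing_gives_100(self, table2):
        agreeing = table2.copy()
        agreeing["ctc_her2_status"] = agreeing["tissue_her2"]
        assert concordance(agreeing).percent == 100

    def test_records_without_ctc_status_excluded(self, table2):
        partial = table2.copy()
        partial.loc[partial.index[:3], "ctc_her2_status"] = None
        c = concordance(partial)
        assert c.n_total == 20

    def test_round_half_up(self):
        assert round_half_up(56.5) == 57
        assert round_half_up(56.49) == 56


def spearman_oracle(x, y):
    """Rank both vectors with mid-ranks, then plain Pearson."""
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


class TestSpearman:
    def test_monotone_gives_one(self):
        x = [1, 2, 3, 4, 5]
        assert spearman_rho(x, [10, 20, 25, 40, 100]) == pytest.approx(1.0)

    def test_tied_data_matches_midrank_pearson_oracle(self, rng):
        for _ in range(20):
            x = rng.integers(0, 4, size=6).astype(float)
            y = rng.integers(0, 4, size=6).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            assert spearman_rho(x, y) == pytest.approx(
                spearman_oracle(x, y), abs=1e-12
            )

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            spearman_rho([1, 1, 1], [1, 2, 3])

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.uniform(1, 10, 30)
        y = rng.uniform(1, 10, 30)
        assert spearman_rho(np.exp(x), y) == pytest.approx(
            spearman_rho(x, y), abs=1e-12
        )


class TestKruskalWallis:
    def test_identical_values_define_h_zero(self):
        h, p = kruskal_wallis([3, 3], [3, 3, 3], [3])
        assert (h, p) == (0.0, 1.0)

    def test_small_groups_match_permutation_null(self, rng):
        groups = [[1.2, 3.4, 2.2], [4.5, 5.1], [0.3, 2.8, 6.0]]
        h_obs, p_chi2 = kruskal_wallis(*groups)
        pooled = np.concatenate(groups)
        sizes = [len(g) for g in groups]
        count = 0
        n_perm = 5_000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            parts = np.split(pooled, np.cumsum(sizes)[:-1])
            h_perm, _ = kruskal_wallis(*parts)
            count += h_perm >= h_obs - 1e-12
        p_perm = count / n_perm
        # chi-square approximation vs exact permutation null at tiny n
        assert p_chi2 == pytest.approx(p_perm, abs=0.05)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([1, 2, 3])


class TestPairwiseRankTest:
    def test_identical_groups_give_one(self):
        assert pairwise_rank_test([2, 2, 2], [2, 2]) == 1.0

    def test_disjoint_support_matches_exact_enumeration(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [10.0, 11.0, 12.0, 13.0, 14.0]
        p = pairwise_rank_test(a, b)
        # oracle: count orderings as extreme as complete separation
        pooled = a + b
        n_extreme = sum(
            1
            for combo in itertools.combinations(range(10), 5)
            if max(combo) < 5 or min(combo) >= 5
        )
        from math import comb

        assert p == pytest.approx(n_extreme / comb(10, 5), rel=1e-9)

    def test_symmetric_in_group_order(self, rng):
        a = rng.uniform(0, 1, 8)
        b = rng.uniform(0, 2, 6)
        assert pairwise_rank_test(a, b) == pytest.approx(
            pairwise_rank_test(b, a)
        )


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate([3.0, 5.0, 8.0], [False, False, False])
        assert (curve.survival == 1.0).all()
        assert curve.median is None
        assert curve.median_label == "not reached"

    def test_no_censoring_median_convention(self):
        curve = km_estimate(list(range(1, 11)), [True] * 10)
        assert curve.median == 5.0

    def test_no_censoring_reproduces_empirical_survival(self, rng):
        t = rng.exponential(10.0, size=40)
        curve = km_estimate(t, [True] * 40)
        for time, surv in zip(curve.times[1:], curve.survival[1:]):
            assert surv == pytest.approx((t > time).mean(), abs=1e-12)

    def test_exponential_median_closed_form(self):
        rng = np.random.default_rng(100)
        t = rng.exponential(1 / 0.1, size=500)
        curve = km_estimate(t, [True] * 500)
        assert curve.median == pytest.approx(np.log(2) / 0.1, rel=0.10)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_give_null(self):
        t = [2.0, 4.0, 6.0, 8.0]
        e = [True, True, False, True]
        chi2, p = logrank_test({"x": (t, e), "y": (t, e)})
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_invariant_under_relabeling(self, rng):
        ga = (rng.exponential(10, 30), np.ones(30, dtype=bool))
        gb = (rng.exponential(5, 30), np.ones(30, dtype=bool))
        chi2_ab, _ = logrank_test({"a": ga, "b": gb})
        chi2_ba, _ = logrank_test({"b": gb, "a": ga})
        assert chi2_ab == pytest.approx(chi2_ba)

    def test_no_events_anywhere_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            logrank_test(
                {"a": ([1.0], [False]), "b": ([2.0], [False])}
            )


class TestChiSquare:
    def test_proportional_table_gives_p_one(self):
        assert categorical_association([[10, 20], [20, 40]]) == pytest.approx(
            1.0
        )

    def test_diagonal_2x2_hand_computed(self):
        # chi2 = sum (O-E)^2/E = 4 * (5^2/5) = 20; expected cells exactly 5
        p = categorical_association([[10, 0], [0, 10]])
        chi2 = stats.chi2.isf(p, df=1)
        assert chi2 == pytest.approx(20.0, rel=1e-6)
        assert p < 1e-4

    def test_small_expected_count_warns(self):
        with pytest.warns(UserWarning, match="expected cell"):
            categorical_association([[3, 1], [1, 3]])

    def test_invariant_under_row_permutation(self):
        t = [[12, 5, 7], [3, 9, 11]]
        assert categorical_association(t) == pytest.approx(
            categorical_association(t[::-1])
        )

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            categorical_association([[0, 0], [1, 2]])


class TestGroupSummaries:
    def test_fixture_group_medians(self, table2):
        summary = group_emt_summary(table2).set_index("stratum")
        assert summary.loc["A'", "median"] == pytest.approx(0.18)
        assert summary.loc["B", "median"] == pytest.approx(0.175)
        assert summary.loc["C", "median"] == pytest.approx(0.15)

    def test_holm_adjustment_monotone(self):
        adj = holm_adjust([0.01, 0.04, 0.03])
        assert adj == pytest.approx([0.03, 0.06, 0.06])
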