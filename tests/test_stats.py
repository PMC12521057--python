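"""Cohort statistics: Friedman, Wilcoxon+Holm, Pearson labels, permutation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import ctnoise.stats as cst
from ctnoise import (
    compare_cohort,
    friedman_omnibus,
    holm_adjust,
    paired_permutation_exam,
    pairwise_wilcoxon_holm,
    pearson_matrix_with_strength,
    strength_label,
    wilcoxon_signed_rank,
)


class TestFriedman:
    def test_identical_columns_degenerate(self):
        stat, p = friedman_omnibus(np.full((5, 3), 7.0))
        assert stat == 0.0 and p == 1.0

    def test_textbook_rank_example(self):
        """Rows (1,2,3): rank sums (3,6,9) give chi-square exactly 6."""
        stat, _ = friedman_omnibus(np.tile([1.0, 2.0, 3.0], (3, 1)))
        assert stat == pytest.approx(6.0, abs=1e-12)

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(10):
            m = rng.normal(10, 3, size=(10, 5))
            stat, p = friedman_omnibus(m)
            ref = sps.friedmanchisquare(*m.T)
            assert stat == pytest.approx(ref.statistic, abs=1e-8)
            assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_missing_cells_rejected(self):
        m = np.ones((4, 3))
        m[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            friedman_omnibus(m)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            friedman_omnibus(np.ones((2, 3)))


class TestWilcoxon:
    def test_all_positive_n6_exact(self):
        """Six positive differences: only 1 of 64 sign patterns as extreme per side."""
        a = np.arange(1.0, 7.0) + 5
        b = np.arange(1.0, 7.0)
        _, p, degen = wilcoxon_signed_rank(a, b)
        assert p == pytest.approx(2 / 64)
        assert not degen

    def test_identical_samples_degenerate(self):
        _, p, degen = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert p == 1.0 and degen

    def test_matches_scipy_exact_path(self, rng):
        for _ in range(10):
            a = rng.normal(0, 1, 12)
            b = rng.normal(0.5, 1, 12)
            _, p, _ = wilcoxon_signed_rank(a, b)
            ref = sps.wilcoxon(a, b)
            assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_matches_scipy_normal_approximation(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.3, 1, 40)
        _, p, _ = wilcoxon_signed_rank(a, b)
        ref = sps.wilcoxon(a, b, correction=True, method="approx")
        assert p == pytest.approx(ref.pvalue, abs=1e-8)


class TestHolm:
    def test_hand_worked_example(self):
        adj = holm_adjust([0.01, 0.04, 0.03])
        assert adj == pytest.approx([0.03, 0.06, 0.06])

    def test_dominates_raw(self, rng):
        p = rng.uniform(0, 1, 8)
        assert (holm_adjust(p) >= p - 1e-15).all()

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10))
    def test_bounded_and_order_preserving(self, pvals):
        adj = holm_adjust(pvals)
        assert ((adj >= 0) & (adj <= 1)).all()
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_pairwise_table_shape_and_flags(self, rng):
        t = pd.DataFrame(rng.normal(size=(12, 4)), columns=list("abcd"))
        out = pairwise_wilcoxon_holm(t, alpha=0.05)
        assert len(out) == 6
        assert (out["p_holm"] >= out["p_raw"] - 1e-15).all()

    def test_degenerate_pair_flagged(self):
        t = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4], "c": [2.0, 3, 4, 5]})
        out = pairwise_wilcoxon_holm(t)
        row = out[(out.metric_a == "a") & (out.metric_b == "b")].iloc[0]
        assert row.degenerate and row.p_raw == 1.0


class TestPearsonStrength:
    @pytest.mark.parametrize(
        "r,label",
        [(1.0, "very strong"), (0.85, "very strong"), (0.7, "strong"),
         (0.55, "moderate"), (0.3, "weak"), (0.1, "very weak/none"),
         (-0.5, "very weak/none"), (float("nan"), "undefined")],
    )
    def test_bins(self, r, label):
        assert strength_label(r) == label

    def test_matrix_symmetric_unit_diagonal(self, rng):
        t = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("wxyz"))
        r, labels = pearson_matrix_with_strength(t)
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)
        assert labels.loc["w", "w"] == "very strong"

    def test_column_vs_its_copy(self, rng):
        x = rng.normal(size=15)
        t = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=15)})
        r, labels = pearson_matrix_with_strength(t)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert labels.loc["a", "b"] == "very strong"

    def test_zero_variance_column_undefined(self, rng):
        t = pd.DataFrame({"a": rng.normal(size=10), "b": np.ones(10)})
        r, labels = pearson_matrix_with_strength(t)
        assert np.isnan(r.loc["a", "b"])
        assert labels.loc["a", "b"] == "undefined"


class TestPairedPermutation:
    def test_all_zero_differences(self):
        assert paired_permutation_exam([1.0, 2.0], [1.0, 2.0]) == 1.0

    def test_two_slices_hand_enumeration(self):
        """Patterns (++,+-,-+,--) give |mean| (1,0,0,1): p = 2/4."""
        assert paired_permutation_exam([2.0, 2.0], [1.0, 1.0]) == 0.5

    def test_twelve_identical_differences(self):
        p = paired_permutation_exam(np.ones(12) * 3, np.ones(12) * 2)
        assert p == pytest.approx(2 / 4096)

    def test_monte_carlo_matches_enumeration(self, rng):
        d = rng.normal(0.4, 1.0, 10)
        exact = paired_permutation_exam(d, np.zeros(10))
        old = cst.EXHAUSTIVE_PERMUTATION_MAX_N
        cst.EXHAUSTIVE_PERMUTATION_MAX_N = 0
        try:
            mc = paired_permutation_exam(d, np.zeros(10), n_perm=50_000, seed=3)
        finally:
            cst.EXHAUSTIVE_PERMUTATION_MAX_N = old
        assert abs(mc - exact) < 0.01

    def test_seed_reproducibility(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0, 1, 30)
        p1 = paired_permutation_exam(a, b, n_perm=2000, seed=9)
        p2 = paired_permutation_exam(a, b, n_perm=2000, seed=9)
        assert p1 == p2

    def test_type_i_error_controlled(self):
        """Null exams (A = B + symmetric noise): ~5% rejections at alpha 0.05."""
        rng = np.random.default_rng(123)
        rejections = 0
        n_exams = 200
        for _ in range(n_exams):
            b = rng.normal(10, 2, 30)
            a = b + rng.normal(0, 1, 30)
            p = paired_permutation_exam(a, b, n_perm=2000, seed=int(rng.integers(2**31)))
            rejections += p < 0.05
        assert 0.02 <= rejections / n_exams <= 0.10


class TestCompareCohort:
    def test_full_report(self, rng):
        cols = ["Duke_tissue_mode", "Wisconsin_tissue_mean", "Wisconsin_tissue_mode",
                "Wisconsin_air_mean", "Wisconsin_air_mode"]
        base = rng.normal(15, 2, 30)
        table = pd.DataFrame(
            {c: base + rng.normal(i, 0.5, 30) for i, c in enumerate(cols)}
        )
        slice_rows = []
        for e in range(4):
            for s in range(8):
                for m in cols[:3]:
                    slice_rows.append(
                        {"exam": f"e{e}", "slice": s, "metric": m,
                         "value": 10 + rng.normal(0, 1)})
        report = compare_cohort(table, pd.DataFrame(slice_rows), n_perm=500, seed=1)
        assert 0 <= report.friedman_p <= 1
        assert len(report.pairwise) == 10
        assert report.permutation_p is not None
        assert set(report.permutation_p.columns) >= {"exam", "p", "significant"}
        d = report.to_dict()
        assert "friedman" in d and "paired_permutation" in d

    def test_constant_shift_pair(self, rng):
        """Metric B = A + 2 exactly: maximal Wilcoxon evidence, r = 1."""
        a = rng.normal(12, 2, 12)
        table = pd.DataFrame({"A": a, "B": a + 2.0, "C": rng.normal(12, 2, 12)})
        out = pairwise_wilcoxon_holm(table)
        row = out[(out.metric_a == "A") & (out.metric_b == "B")].iloc[0]
        assert row.p_raw == pytest.approx(2 / 2**12)
        r, _ = pearson_matrix_with_strength(table)
        assert r.loc["A", "B"] == pytest.approx(1.0)

    def test_missing_slice_records_noted(self, rng):
        table = pd.DataFrame(rng.normal(10, 1, size=(6, 3)), columns=list("abc"))
        report = compare_cohort(table, None)
        assert report.permutation_p is None
        assert any("omitted" in n for n in report.notes)
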