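"""ICC(A,1), group tests, asymmetry and p-value adjustment."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import stereovalid as sv
from stereovalid.agreement import DegenerateTableError


def brute_force_icc(table):
    """Independent oracle: cell-mean two-way decomposition written out longhand."""
    x = np.asarray(table, float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    msr = sum(k * (x[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n) for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


class TestICC:
    def test_identical_columns_give_one(self):
        table = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        res = sv.icc_absolute_agreement(table)
        assert res.icc == pytest.approx(1.0)
        assert res.mse == 0.0

    def test_worked_offset_table(self):
        # rater2 = rater1 + 1: MSR = 13.333, MSC = 2, MSE = 0
        res = sv.icc_absolute_agreement([[1, 2], [3, 4], [5, 6], [7, 8]])
        assert res.msr == pytest.approx(40.0 / 3.0)
        assert res.msc == pytest.approx(2.0)
        assert res.mse == pytest.approx(0.0, abs=1e-12)
        assert res.icc == pytest.approx(13.333333 / 14.333333, rel=1e-6)
        assert res.ci_lower <= res.icc <= res.ci_upper

    def test_constant_offset_decreases_icc(self, rng):
        base = rng.normal(7000, 600, (12, 2))
        base[:, 1] = base[:, 0] + rng.normal(0, 50, 12)
        icc0 = sv.icc_absolute_agreement(base).icc
        shifted = base.copy()
        shifted[:, 1] += 400.0
        assert sv.icc_absolute_agreement(shifted).icc < icc0

    def test_exhaustive_small_integer_tables_match_oracle(self):
        # every 3x2 table over {1,2,3} plus a systematic family of 4x3 and
        # 6x3 tables; agreement with the longhand decomposition to 1e-10
        checked = 0
        for cells in itertools.product([1, 2, 3], repeat=6):
            table = np.array(cells, float).reshape(3, 2)
            if np.allclose(table.mean(axis=1), table.mean()):
                continue  # degenerate: no between-subject variance
            assert sv.icc_absolute_agreement(table).icc == pytest.approx(
                brute_force_icc(table), abs=1e-10)
            checked += 1
        rng = np.random.default_rng(17)
        for n, k in ((4, 3), (6, 3)):
            for _ in range(200):
                table = rng.integers(1, 7, size=(n, k)).astype(float)
                try:
                    res = sv.icc_absolute_agreement(table)
                except DegenerateTableError:
                    continue
                assert res.icc == pytest.approx(brute_force_icc(table), abs=1e-10)
                checked += 1
        assert checked > 700

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        truth = rng.normal(7000, 600, 15)
        table = truth[:, None] + rng.normal(0, 120, (15, 3))
        table[:, 2] += 90.0
        long = (pd.DataFrame(table, columns=list("abc"))
                .reset_index().melt("index", var_name="rater", value_name="v"))
        ref = pg.intraclass_corr(long, targets="index", raters="rater",
                                 ratings="v")
        ref_row = ref[ref.Type == "ICC(A,1)"].iloc[0]
        mine = sv.icc_absolute_agreement(table)
        assert mine.icc == pytest.approx(ref_row["ICC"], abs=1e-9)
        lo, hi = ref_row["CI95"]
        assert mine.ci_lower == pytest.approx(lo, abs=0.01)
        assert mine.ci_upper == pytest.approx(hi, abs=0.01)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(scale=st.floats(0.1, 100.0), seed=st.integers(0, 50))
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        table = rng.normal(10, 3, (8, 3))
        try:
            base = sv.icc_absolute_agreement(table).icc
        except DegenerateTableError:
            return
        assert sv.icc_absolute_agreement(scale * table).icc == pytest.approx(
            base, abs=1e-9)

    def test_degenerate_table_raises(self):
        with pytest.raises(DegenerateTableError):
            sv.icc_absolute_agreement([[3.0, 3.0], [3.0, 3.0]])

    def test_too_small_table_rejected(self):
        with pytest.raises(ValueError):
            sv.icc_absolute_agreement([[1.0, 2.0]])


class TestGroupTests:
    def test_identical_groups_null_results(self):
        res_f = sv.anova_between([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res_f.statistic == 0.0 and res_f.pvalue == 1.0
        res_t = sv.two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res_t.statistic == 0.0

    def test_hand_anova_oracle(self):
        # {1,2,3} vs {4,5,6}: SSB = 13.5, MSW = 1 -> F = 13.5 on (1, 4)
        res = sv.anova_between([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(13.5, abs=1e-12)
        assert res.df == (1.0, 4.0)
        assert res.pvalue == pytest.approx(float(sps.f.sf(13.5, 1, 4)), rel=1e-12)
        t = sv.two_sample_t([1, 2, 3], [4, 5, 6])
        assert t.statistic**2 == pytest.approx(13.5, abs=1e-10)

    def test_f_equals_t_squared(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(3, 12))
            b = rng.normal(0.3, 1.5, rng.integers(3, 12))
            f = sv.anova_between(a, b).statistic
            t = sv.two_sample_t(a, b).statistic
            assert f == pytest.approx(t**2, abs=1e-10)
            assert sv.anova_between(a, b).pvalue == pytest.approx(
                sv.two_sample_t(a, b).pvalue, abs=1e-12)

    def test_t_antisymmetric_in_group_order(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 5.0, 6.0]
        fwd = sv.two_sample_t(a, b)
        rev = sv.two_sample_t(b, a)
        assert fwd.statistic == pytest.approx(-rev.statistic)
        assert fwd.pvalue == pytest.approx(rev.pvalue)

    def test_zero_within_variance_flagged(self):
        res = sv.anova_between([1.0, 1.0], [2.0, 2.0])
        assert np.isinf(res.statistic) and res.pvalue == 0.0 and res.degenerate

    def test_matches_scipy_f_oneway(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.5, 1, 15)
        ref = sps.f_oneway(a, b)
        res = sv.anova_between(a, b)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-9)

    def test_null_pvalues_are_uniform(self, rng):
        # 2000 null datasets; KS against U(0,1) at alpha = 0.01
        pvals = []
        for _ in range(2000):
            a = rng.normal(7000, 800, 20)
            b = rng.normal(7000, 800, 10)
            pvals.append(sv.anova_between(a, b).pvalue)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestAsymmetryAndAdjustment:
    def test_asymmetry_examples(self):
        assert sv.asymmetry_index(100.0, 100.0) == 0.0
        assert sv.asymmetry_index(110.0, 90.0) == pytest.approx(20.0)
        assert sv.asymmetry_index(90.0, 110.0) == pytest.approx(-20.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(left=st.floats(1e-3, 1e5), right=st.floats(1e-3, 1e5))
    def test_asymmetry_antisymmetric_and_bounded(self, left, right):
        fwd = sv.asymmetry_index(left, right)
        assert fwd == pytest.approx(-sv.asymmetry_index(right, left), rel=1e-9)
        assert -200.0 < fwd < 200.0

    def test_asymmetry_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            sv.asymmetry_index(-1.0, 2.0)

    def test_bonferroni_examples(self):
        np.testing.assert_allclose(
            sv.adjust_pvalues([0.01, 0.02], "bonferroni"), [0.02, 0.04])
        np.testing.assert_allclose(sv.adjust_pvalues([0.3]), [0.3])
        assert sv.adjust_pvalues([0.9, 0.8], "bonferroni").max() == 1.0

    def test_holm_dominates_bonferroni(self):
        # hand enumeration for [0.01, 0.04, 0.03]:
        # Holm: sorted (0.01, 0.03, 0.04) -> (0.03, 0.06, 0.06)
        p = [0.01, 0.04, 0.03]
        holm = sv.adjust_pvalues(p, "holm")
        bonf = sv.adjust_pvalues(p, "bonferroni")
        np.testing.assert_allclose(holm, [0.03, 0.06, 0.06])
        np.testing.assert_allclose(bonf, [0.03, 0.12, 0.09])
        assert np.all(holm <= bonf)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            sv.adjust_pvalues([0.5, 1.2])
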