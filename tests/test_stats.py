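import numpy as np
import pandas as pd
import pytest

from thermorun.stats import (correlate, rmcorr, icc, median_split,
                             section_icc_report, holm_bonferroni)

from oracles import icc_anova_loops, rmcorr_design_matrix


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = correlate(x, 2 * x)
        assert res.r == pytest.approx(1.0)
        assert res.magnitude_label == "large"

    def test_spearman_perfect_inverse(self):
        x = np.array([1.0, 4.0, 2.0, 9.0, 7.0])
        res = correlate(x, -x, method="spearman")
        assert res.r == pytest.approx(-1.0)

    def test_matches_bruteforce_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            res = correlate(x, y)
            num = np.sum((x - x.mean()) * (y - y.mean()))
            den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
            assert res.r == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            correlate(np.ones(5), np.arange(5.0))

    @pytest.mark.parametrize("r,label", [(0.05, "trivial"), (0.1, "small"),
                                         (0.29, "small"), (0.3, "moderate"),
                                         (0.49, "moderate"), (0.5, "large"),
                                         (-0.6, "large")])
    def test_cohen_bands(self, r, label):
        from thermorun.stats import _cohen_label
        assert _cohen_label(r) == label


class TestRmcorr:
    def test_perfect_within_subject_fit(self):
        subs = np.repeat([0, 1, 2], 5)
        x = np.tile(np.arange(5.0), 3)
        y = x + np.repeat([0.0, 10.0, -5.0], 5)   # subject offsets only
        res = rmcorr(subs, x, y, n_boot=50, seed=0)
        assert res.r_rm == pytest.approx(1.0)
        assert res.df == 15 - 3 - 1

    def test_degenerate_constant_x(self):
        subs = np.repeat([0, 1], 4)
        x = np.repeat([2.0, 5.0], 4)   # constant within each subject
        y = np.arange(8.0)
        with pytest.raises(ValueError, match="degenerate"):
            rmcorr(subs, x, y)

    def test_matches_design_matrix_oracle(self):
        """r_rm equals explicit dummy-coded ANCOVA least squares to 1e-10."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            ns = int(rng.integers(2, 6))
            npts = int(rng.integers(3, 8))
            subs = np.repeat(np.arange(ns), npts)
            x = rng.normal(size=subs.size) + subs * rng.normal()
            y = rng.normal() * x + rng.normal(size=subs.size) + 2.0 * subs
            res = rmcorr(subs, x, y, n_boot=2, seed=0)
            assert res.r_rm == pytest.approx(rmcorr_design_matrix(subs, x, y), abs=1e-10)

    def test_ci_brackets_estimate_and_deterministic(self):
        rng = np.random.default_rng(2)
        subs = np.repeat(np.arange(6), 8)
        x = rng.normal(size=48)
        y = 0.7 * x + rng.normal(size=48) * 0.5 + np.repeat(rng.normal(size=6), 8)
        a = rmcorr(subs, x, y, n_boot=200, seed=3)
        b = rmcorr(subs, x, y, n_boot=200, seed=3)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert a.ci_low <= a.r_rm <= a.ci_high

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        subs = np.repeat(np.arange(4), 6)
        x = rng.normal(size=24)
        y = 0.5 * x + rng.normal(size=24) + np.repeat(rng.normal(size=4), 6)
        res = rmcorr(subs, x, y, n_boot=2, seed=0)
        ref = pg.rm_corr(pd.DataFrame({"s": subs, "x": x, "y": y}),
                         x="x", y="y", subject="s")
        assert res.r_rm == pytest.approx(ref.r.values[0], abs=1e-10)
        assert res.p_value == pytest.approx(ref.pval.values[0], abs=1e-10)
        assert res.df == int(ref.dof.values[0])


class TestICC:
    def test_identical_columns_unity(self):
        col = np.arange(8.0)
        m = np.column_stack([col, col, col])
        assert icc(m, "consistency").icc == pytest.approx(1.0)
        assert icc(m, "agreement").icc == pytest.approx(1.0)

    def test_constant_shift_consistency_vs_agreement(self):
        col = np.arange(8.0)
        m = np.column_stack([col, col + 2.0])
        assert icc(m, "consistency").icc == pytest.approx(1.0)
        assert icc(m, "agreement").icc < 1.0

    def test_matches_anova_loop_oracle(self):
        """Both forms equal explicit sum-of-squares loops to 1e-10."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(4, 10))
            k = int(rng.integers(2, 5))
            m = rng.normal(size=(n, k)) + 1.5 * rng.normal(size=(n, 1))
            for form in ("consistency", "agreement"):
                assert icc(m, form).icc == pytest.approx(
                    icc_anova_loops(m, form), abs=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        m = rng.normal(size=(9, 3)) + 2 * rng.normal(size=(9, 1))
        df = pd.DataFrame({"t": np.repeat(np.arange(9), 3),
                           "r": np.tile(np.arange(3), 9), "s": m.ravel()})
        ref = pg.intraclass_corr(df, targets="t", raters="r", ratings="s").set_index("Type")
        assert icc(m, "consistency").icc == pytest.approx(
            ref.loc["ICC(C,1)", "ICC"], abs=1e-12)
        assert icc(m, "agreement").icc == pytest.approx(
            ref.loc["ICC(A,1)", "ICC"], abs=1e-12)

    def test_column_constant_invariance_consistency_only(self):
        rng = np.random.default_rng(7)
        m = rng.normal(size=(10, 3)) + rng.normal(size=(10, 1))
        shifts = np.array([0.0, 1.0, -2.0])
        c0 = icc(m, "consistency").icc
        c1 = icc(m + shifts, "consistency").icc
        a0 = icc(m, "agreement").icc
        a1 = icc(m + shifts, "agreement").icc
        assert c1 == pytest.approx(c0, abs=1e-12)
        assert a1 < a0

    def test_rows_with_missing_dropped(self):
        rng = np.random.default_rng(8)
        m = rng.normal(size=(10, 3)) + rng.normal(size=(10, 1))
        m2 = m.copy()
        m2[3, 1] = np.nan
        res = icc(m2, "consistency")
        assert res.n_rows == 9
        ref = icc(np.delete(m, 3, axis=0), "consistency")
        assert res.icc == pytest.approx(ref.icc)

    @pytest.mark.parametrize("value,label", [(0.49, "poor"), (0.5, "moderate"),
                                             (0.75, "moderate"), (0.76, "good"),
                                             (0.9, "good"), (0.91, "excellent")])
    def test_koo_li_bands(self, value, label):
        from thermorun.stats import _koo_li_label
        assert _koo_li_label(value) == label

    def test_degenerate_input(self):
        with pytest.raises(ValueError):
            icc(np.ones((1, 3)), "consistency")


class TestMedianSplit:
    def test_eleven_values_six_five(self):
        vals = {f"P{i}": float(i) for i in range(11)}
        low, high = median_split(vals)
        assert len(low) == 6 and len(high) == 5
        assert set(low) == {f"P{i}" for i in range(6)}

    def test_sorted_halves(self):
        vals = {"a": 3.0, "b": 1.0, "c": 2.0, "d": 4.0}
        low, high = median_split(vals)
        assert low == ["b", "c"] and high == ["a", "d"]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        keys = [f"P{i}" for i in range(9)]
        vals = dict(zip(keys, rng.normal(size=9)))
        ref = median_split(vals)
        shuffled = dict(sorted(vals.items(), key=lambda kv: hash(kv[0])))
        assert median_split(shuffled) == ref


class TestHolm:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(13)
        p = rng.uniform(0, 0.2, size=12)
        _, ref, _, _ = multipletests(p, method="holm")
        assert np.allclose(holm_bonferroni(p), ref, atol=1e-12)

    def test_monotone_and_bounded(self):
        p = np.array([0.001, 0.04, 0.03, 0.5])
        adj = holm_bonferroni(p)
        assert np.all(adj >= p)
        assert np.all(adj <= 1.0)


class TestSectionReport:
    def test_duplicated_sessions_unity(self):
        col = np.linspace(30.0, 29.0, 50)
        data = {"P1": {"WU": np.column_stack([col, col, col])}}
        tbl = section_icc_report(data)
        valid = tbl[(tbl.participant == "P1") & tbl.valid]
        assert np.allclose(valid["icc"].to_numpy(), 1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(10)
        m = rng.normal(size=(500, 3))
        tbl = section_icc_report({"P1": {"WU": m}})
        icc_val = tbl[(tbl.participant == "P1") & (tbl.form == "ICC(3,1)")].icc.values[0]
        assert abs(icc_val) < 0.2

    def test_cells_equal_direct_icc_calls(self):
        rng = np.random.default_rng(11)
        m1 = rng.normal(size=(40, 3)) + np.linspace(0, 2, 40)[:, None]
        m2 = rng.normal(size=(30, 3)) + np.linspace(0, 1, 30)[:, None]
        tbl = section_icc_report({"P1": {"WU": m1}, "P2": {"WU": m2}})
        got = tbl[(tbl.participant == "P1") & (tbl.form == "ICC(3,1)")].icc.values[0]
        assert got == pytest.approx(icc(m1, "consistency").icc)

    def test_missing_section_flagged_not_fatal(self):
        rng = np.random.default_rng(12)
        tbl = section_icc_report({"P1": {"WU": rng.normal(size=(20, 3))},
                                  "P2": {"WU": None}})
        row = tbl[(tbl.participant == "P2")]
        assert (~row["valid"]).all()
        assert (tbl[tbl.participant == "P1"]["valid"]).all()
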