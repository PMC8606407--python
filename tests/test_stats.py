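"""Inferential procedures against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from microexplore import (LmmSpec, fit_lmm, icc, one_sample_t, paired_t,
                          pearson_corr, percbend_corr)
from microexplore.stats import DegenerateDataError
from microexplore.metrics import sqrt_transform


def percbend_oracle(x, y, beta=0.2):
    """Step-by-step scalar-loop reference, independent of the vector code."""
    n = len(x)

    def margin(v):
        sv = sorted(v)
        mid = n // 2
        M = sv[mid] if n % 2 else 0.5 * (sv[mid - 1] + sv[mid])
        W = sorted(abs(vi - M) for vi in v)
        m = int(math.floor((1 - beta) * n + 0.5))
        omega = W[m - 1]
        i1 = sum(1 for vi in v if (vi - M) / omega < -1)
        i2 = sum(1 for vi in v if (vi - M) / omega > 1)
        sum_mid = sum(vi for vi in v if abs((vi - M) / omega) <= 1)
        phi = (omega * (i2 - i1) + sum_mid) / (n - i1 - i2)
        return [max(-1.0, min(1.0, (vi - phi) / omega)) for vi in v]

    A, B = margin(list(x)), margin(list(y))
    num = sum(a * b for a, b in zip(A, B))
    den = math.sqrt(sum(a * a for a in A) * sum(b * b for b in B))
    return num / den


class TestLocationTests:
    def test_one_sample_symmetry_gives_t_zero(self):
        res = one_sample_t([-1.0, 1.0], mu=0)
        assert res.statistic == 0 and res.p_value == 1

    def test_one_sample_matches_textbook_formula(self):
        rng = np.random.default_rng(21)
        v = rng.normal(5, 2, size=37)
        res = one_sample_t(v, mu=4.2)
        mean = sum(v) / len(v)
        sd = math.sqrt(sum((x - mean) ** 2 for x in v) / (len(v) - 1))
        t = (mean - 4.2) / (sd / math.sqrt(len(v)))
        assert res.statistic == pytest.approx(t, abs=1e-12)
        ref = sps.ttest_1samp(v, 4.2)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)
        assert res.df == len(v) - 1

    def test_zero_variance_flags_degenerate(self):
        with pytest.raises(DegenerateDataError):
            one_sample_t([3.0, 3.0, 3.0])

    def test_paired_equal_arrays_degenerate(self):
        with pytest.raises(DegenerateDataError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_paired_constant_offset_degenerate(self):
        a = np.array([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateDataError):
            paired_t(a + 0.5, a)

    def test_paired_matches_difference_formula(self):
        rng = np.random.default_rng(22)
        a = rng.normal(size=25)
        b = a * 0.5 + rng.normal(size=25)
        res = paired_t(a, b)
        ref = sps.ttest_rel(a, b)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_paired_drops_incomplete_pairs(self):
        a = np.array([1.0, np.nan, 3.0, 4.0, 6.0])
        b = np.array([0.5, 2.0, np.nan, 1.0, 2.0])
        res = paired_t(a, b)
        assert res.n == 3


class TestPercbend:
    def test_identity_and_antisymmetry(self):
        x = np.random.default_rng(1).normal(size=20)
        assert percbend_corr(x, x).estimate == 1.0
        assert percbend_corr(x, -x).estimate == -1.0

    def test_matches_stepwise_oracle_on_200_samples(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(8, 51))
            x = rng.normal(size=n) + rng.standard_t(3, size=n)
            y = 0.5 * x + rng.normal(size=n)
            mine = percbend_corr(x, y).estimate
            assert mine == pytest.approx(percbend_oracle(x, y), abs=1e-12)
            assert -1 <= mine <= 1

    def test_matches_published_reference_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(43)
        checked = 0
        for _ in range(100):
            n = int(rng.integers(8, 51))
            # the reference uses int((1-beta)n) for the bend-scale order
            # statistic; compare where that coincides with floor(.+0.5)
            if int(0.8 * n) != int(math.floor(0.8 * n + 0.5)):
                continue
            x = rng.normal(size=n)
            y = 0.3 * x + rng.normal(size=n)
            ref = pingouin.corr(x, y, method="percbend")
            assert percbend_corr(x, y).estimate == pytest.approx(
                float(ref["r"].iloc[0]), abs=1e-8)
            checked += 1
        assert checked > 20

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(44)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        base = percbend_corr(x, y).estimate
        assert percbend_corr(x + 100, y - 7).estimate == pytest.approx(
            base, abs=1e-12)
        assert percbend_corr(x * 3.5, y * 0.2).estimate == pytest.approx(
            base, abs=1e-12)

    def test_robustness_contract_vs_pearson(self):
        """One 100-SD outlier barely moves the bend estimate but wrecks
        Pearson on the same strongly correlated n=30 fixture."""
        rng = np.random.default_rng(45)
        x = rng.normal(size=30)
        y = x + 0.3 * rng.normal(size=30)
        pb0 = percbend_corr(x, y).estimate
        pe0 = pearson_corr(x, y).estimate
        y2 = y.copy()
        y2[0] = y.mean() - 100 * y.std(ddof=1)
        assert abs(percbend_corr(x, y2).estimate - pb0) < 0.15
        assert abs(pearson_corr(x, y2).estimate - pe0) > 0.3

    def test_massive_median_ties_flag_degenerate_scale(self):
        x = np.array([5.0] * 18 + [1.0, 9.0])
        y = np.arange(20, dtype=float)
        with pytest.raises(DegenerateDataError):
            percbend_corr(x, y)


class TestPearson:
    def test_exact_lines(self):
        x = np.arange(10, dtype=float)
        assert pearson_corr(x, x).estimate == pytest.approx(1.0)
        assert pearson_corr(x, -x).estimate == pytest.approx(-1.0)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(46)
        x = rng.normal(size=40)
        y = 0.4 * x + rng.normal(size=40)
        r = sum((x - x.mean()) * (y - y.mean())) / math.sqrt(
            sum((x - x.mean()) ** 2) * sum((y - y.mean()) ** 2))
        assert pearson_corr(x, y).estimate == pytest.approx(r, abs=1e-12)

    def test_degenerate_variance(self):
        with pytest.raises(DegenerateDataError):
            pearson_corr([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestIcc:
    def test_identical_raters_give_one(self):
        r1 = np.random.default_rng(47).normal(size=10)
        tab = pd.DataFrame({"r1": r1, "r2": r1})
        assert icc(tab).estimate == pytest.approx(1.0)

    def test_constant_rater_shift_contrast(self):
        r1 = np.random.default_rng(48).normal(size=12)
        tab = pd.DataFrame({"r1": r1, "r2": r1 + 2.0})
        assert icc(tab, model="consistency").estimate == pytest.approx(1.0)
        assert icc(tab, model="agreement").estimate < 1.0

    def test_matches_anova_decomposition_oracle(self):
        rng = np.random.default_rng(49)
        n, k = 15, 4
        mat = rng.normal(size=(n, k)) + rng.normal(size=(n, 1)) * 1.5
        # mean-squares oracle, written out longhand
        grand = mat.mean()
        msr = k * sum((mat[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
        msc = n * sum((mat[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
        sse = sum((mat[i, j] - mat[i].mean() - mat[:, j].mean() + grand) ** 2
                  for i in range(n) for j in range(k))
        mse = sse / ((n - 1) * (k - 1))
        cons = (msr - mse) / (msr + (k - 1) * mse)
        agree = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        tab = pd.DataFrame(mat)
        assert icc(tab).estimate == pytest.approx(cons, abs=1e-10)
        assert icc(tab, model="agreement").estimate == pytest.approx(
            agree, abs=1e-10)

    def test_matches_reference_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(50)
        mat = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1)) * 2
        long = (pd.DataFrame(mat, columns=list("abc"))
                .reset_index().melt(id_vars="index", var_name="rater",
                                    value_name="score"))
        ref = pingouin.intraclass_corr(long, targets="index", raters="rater",
                                       ratings="score").set_index("Type")
        assert icc(pd.DataFrame(mat)).estimate == pytest.approx(
            ref.loc["ICC(C,1)", "ICC"], abs=1e-8)
        assert icc(pd.DataFrame(mat), model="agreement").estimate == \
            pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-8)


class TestSqrtTransform:
    def test_elementwise_values(self):
        np.testing.assert_allclose(sqrt_transform([0.0, 4.0, 2.25]),
                                   [0.0, 2.0, 1.5])

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            sqrt_transform([1.0, -0.5])


class TestFitLmm:
    @staticmethod
    def _balanced_data(re_sd=0.0, seed=51, n_part=20):
        rng = np.random.default_rng(seed)
        rows = []
        intercepts = rng.normal(0, re_sd, size=n_part)
        for i in range(n_part):
            cond = ["Easy", "Hard", "Impossible"][i % 3]
            for trial in (1, 2, 3):
                for t in range(5):
                    y = (2.0 + 1.5 * trial + 0.3 * t + intercepts[i]
                         + rng.normal(0, 0.5))
                    rows.append({"participant_id": f"p{i}", "condition": cond,
                                 "trial_number": trial, "time_s": float(t),
                                 "trial_length": 20.0 + i,
                                 "motor_score": 12 + i % 5, "y": y})
        return pd.DataFrame(rows)

    def test_reduces_to_ols_with_zero_random_variance(self):
        import statsmodels.formula.api as smf
        data = self._balanced_data(re_sd=0.0)
        spec = LmmSpec(response="y")
        res = {r.term: r for r in fit_lmm(data, spec)}
        ols = smf.ols(spec.formula(), data).fit()
        for term, est in ols.params.items():
            assert res[term].estimate == pytest.approx(est, abs=1e-6)

    def test_recovers_planted_trial_slope(self):
        data = self._balanced_data(re_sd=1.0, seed=52)
        res = {r.term: r for r in fit_lmm(data, LmmSpec(response="y"))}
        assert res["trial_number"].estimate == pytest.approx(1.5, abs=0.3)
        assert res["trial_number"].p_value < 0.05

    def test_baseline_reparameterisation_same_fit(self):
        """Changing the reference condition re-parameterises without
        changing the fitted trial effect."""
        data = self._balanced_data(re_sd=0.7, seed=53)
        res_easy = {r.term: r for r in fit_lmm(
            data, LmmSpec(response="y", reference="Easy"))}
        res_hard = {r.term: r for r in fit_lmm(
            data, LmmSpec(response="y", reference="Hard"))}
        assert res_easy["trial_number"].estimate == pytest.approx(
            res_hard["trial_number"].estimate, abs=1e-4)

    def test_zero_response_flagged_degenerate(self):
        data = self._balanced_data()
        data["y"] = 0.0
        res = fit_lmm(data, LmmSpec(response="y"))
        assert all(r.estimate == 0 for r in res)
        assert all("degenerate" in r.notes for r in res)

    def test_missing_rows_dropped_and_logged(self):
        data = self._balanced_data(re_sd=0.5, seed=54)
        data.loc[:9, "y"] = np.nan
        res = fit_lmm(data, LmmSpec(response="y"))
        assert all("dropped=10" in r.notes for r in res)
        assert res[0].n == len(data) - 10
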