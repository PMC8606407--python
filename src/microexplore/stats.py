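"""Inferential layer: location tests, mixed models, robust correlation, ICC.

The workhorse statistics are classical (one-sample / paired t, Pearson,
random-intercept linear mixed models via statsmodels).  The 20%
percentage-bend correlation is implemented here from its defining algorithm
because it is the robust estimator the analysis pipeline is built around:
it median-centres each margin, scales by a beta-quantile of the absolute
deviations, clamps the standardised scores to [-1, 1] and correlates the
clamped scores, which bounds the influence of the most extreme (1 - beta)
fraction of either margin.

Every procedure returns a :class:`StatResult` so downstream reporting is
uniform: method label, estimate, SE, test statistic, df, two-sided p, n.
No multiple-testing correction is applied anywhere; reports annotate the
number of tests run instead.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class DegenerateDataError(ValueError):
    """Raised when a statistic is undefined (zero variance / zero scale)."""


@dataclasses.dataclass(frozen=True)
class StatResult:
    """Uniform container for one inferential result (or one coefficient)."""

    method: str
    estimate: float
    se: float
    statistic: float
    df: float
    p_value: float
    n: int
    term: str = ""
    notes: str = ""

    def as_row(self) -> dict:
        return dataclasses.asdict(self)


def results_table(results: Sequence[StatResult]) -> pd.DataFrame:
    """One row per test/coefficient, annotated with the total test count."""
    df = pd.DataFrame([r.as_row() for r in results])
    df["n_tests_in_report"] = len(results)
    return df


# ---------------------------------------------------------------------------
# Location tests


def one_sample_t(values, mu: float = 0.0) -> StatResult:
    """Classical one-sample t of the mean against ``mu`` (two-sided)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    n = arr.size
    if n < 2:
        raise DegenerateDataError(f"need >= 2 finite values, got {n}")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero variance: t statistic undefined")
    se = sd / math.sqrt(n)
    t = (arr.mean() - mu) / se
    p = 2 * sps.t.sf(abs(t), df=n - 1)
    return StatResult("one_sample_t", float(arr.mean() - mu), float(se),
                      float(t), float(n - 1), float(p), n)


def paired_t(a, b) -> StatResult:
    """Paired t: one-sample t on the pairwise-complete differences a - b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        raise DegenerateDataError("fewer than 2 complete pairs")
    res = one_sample_t(a[ok] - b[ok], mu=0.0)
    return dataclasses.replace(res, method="paired_t")


# ---------------------------------------------------------------------------
# Correlations


def percbend_corr(x, y, beta: float = 0.2) -> StatResult:
    """Percentage-bend correlation with bend fraction ``beta`` (default 20%).

    Algorithm (per margin v): with M = median(v) and W_i = |v_i - M|, the
    bend scale omega is the m-th order statistic of W where
    m = floor((1 - beta) n + 0.5).  The bend location is
    phi = (omega (i2 - i1) + sum of v_i with |(v_i - M)/omega| <= 1) /
    (n - i1 - i2), where i1/i2 count observations falling below/above the
    +-1 band.  Scores A_i = clamp((x_i - phi_x)/omega_x, -1, 1) (B_i for y)
    are then correlated:  rho_pb = sum A_i B_i / sqrt(sum A_i^2 sum B_i^2),
    with T = rho sqrt((n-2)/(1-rho^2)) on n-2 df, two-sided.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise DegenerateDataError(f"need >= 4 complete pairs, got {n}")

    def bend(v):
        M = np.median(v)
        W = np.sort(np.abs(v - M))
        m = int(math.floor((1.0 - beta) * n + 0.5))
        omega = W[m - 1]
        if omega == 0:
            raise DegenerateDataError(
                "bend scale is zero: too many ties at the median")
        u = (v - M) / omega
        i1 = int(np.sum(u < -1.0))
        i2 = int(np.sum(u > 1.0))
        phi = (omega * (i2 - i1) + v[np.abs(u) <= 1.0].sum()) / (n - i1 - i2)
        return np.clip((v - phi) / omega, -1.0, 1.0)

    A = bend(x)
    B = bend(y)
    denom = math.sqrt(float(A @ A) * float(B @ B))
    if denom == 0:
        raise DegenerateDataError("all bend scores are zero")
    rho = float(A @ B) / denom
    rho = min(1.0, max(-1.0, rho))
    if abs(rho) == 1.0:
        t, p = math.inf * math.copysign(1, rho), 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2 * sps.t.sf(abs(t), df=n - 2)
    se = math.sqrt((1 - rho * rho) / (n - 2)) if abs(rho) < 1 else 0.0
    return StatResult("percbend_corr", rho, se, float(t), float(n - 2),
                      float(p), n, notes=f"beta={beta}")


def pearson_corr(x, y) -> StatResult:
    """Classical Pearson correlation, pairwise-complete, two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise DegenerateDataError(f"need >= 3 complete pairs, got {n}")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise DegenerateDataError("zero variance in a margin")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    t = r * math.sqrt((n - 2) / (1 - r * r)) if abs(r) < 1 else math.inf
    se = math.sqrt((1 - r * r) / (n - 2)) if abs(r) < 1 else 0.0
    return StatResult("pearson_corr", r, se, float(t), float(n - 2),
                      float(res.pvalue), n)


# ---------------------------------------------------------------------------
# Mixed models


@dataclasses.dataclass
class LmmSpec:
    """Fixed-effect structure of a random-intercept mixed model.

    ``fixed`` lists term names; ``condition`` is treatment-coded with
    ``reference`` as baseline (the easy-demonstration condition by default).
    Interactions are written ``a:b``.  Participants always enter as random
    intercepts.
    """

    response: str
    fixed: tuple[str, ...] = ("condition", "trial_number", "time_s",
                              "trial_number:time_s", "trial_length",
                              "motor_score")
    group: str = "participant_id"
    reference: str = "Easy"

    def formula(self) -> str:
        terms = []
        for t in self.fixed:
            if t == "condition":
                terms.append(f"C(condition, Treatment('{self.reference}'))")
            elif ":" in t:
                terms.append(t.replace("condition",
                                       f"C(condition, Treatment('{self.reference}'))"))
            else:
                terms.append(t)
        return f"{self.response} ~ " + " + ".join(terms)


def fit_lmm(data: pd.DataFrame, spec: LmmSpec) -> list[StatResult]:
    """Fit a random-intercept linear mixed model, one StatResult per term.

    Rows with missing values in any model column are dropped (listwise) and
    the count is recorded in each result's notes.  Degrees of freedom are a
    residual-type approximation (n_obs - n_fixed); exact small-sample df
    methods are not attempted.  A singular (zero-variance) random intercept
    is reported as a note, not an error.
    """
    import statsmodels.formula.api as smf

    cols = {spec.response, spec.group}
    for t in spec.fixed:
        cols.update(t.split(":"))
    cols &= set(data.columns)
    sub = data[sorted(cols)].dropna()
    n_dropped = len(data) - len(sub)
    if sub[spec.group].nunique() < 2:
        raise ValueError("need >= 2 participants")
    if float(np.nanstd(sub[spec.response].to_numpy(dtype=float))) == 0:
        return [StatResult("lmm", 0.0, 0.0, 0.0, float(len(sub) - 1), 1.0,
                           len(sub), term=t,
                           notes="degenerate: response has zero variance")
                for t in ("Intercept", *spec.fixed)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(spec.formula(), sub, groups=sub[spec.group])
        fit = None
        for method in ("powell", "cg", "nm"):
            try:
                cand = model.fit(reml=True, method=method)
            except np.linalg.LinAlgError:
                continue
            fit = cand
            if cand.converged:
                break
        if fit is None:
            raise RuntimeError(
                f"mixed model failed for {spec.formula()!r}: singular fit")
    if not fit.converged:
        raise RuntimeError(
            f"mixed model did not converge for {spec.formula()!r}")
    notes = f"dropped={n_dropped}"
    re_var = float(fit.cov_re.iloc[0, 0]) if fit.cov_re.size else 0.0
    if re_var <= 1e-10:
        notes += "; singular: random-intercept variance ~ 0"
    k = len(fit.fe_params)
    df_resid = len(sub) - k
    out = []
    for term in fit.fe_params.index:
        est = float(fit.fe_params[term])
        se = float(fit.bse_fe[term])
        t = est / se if se > 0 else 0.0
        p = 2 * sps.t.sf(abs(t), df=df_resid)
        out.append(StatResult("lmm", est, se, float(t), float(df_resid),
                              float(p), len(sub), term=term, notes=notes))
    return out


# ---------------------------------------------------------------------------
# Reliability


def icc(ratings: pd.DataFrame, model: str = "consistency") -> StatResult:
    """Intraclass correlation of a complete subjects x raters table.

    Two-way single-rater forms from the classical ANOVA decomposition:
    ``model="consistency"`` (raters as fixed effects) and
    ``model="agreement"`` (raters as random effects, absolute agreement).
    Consistency is invariant to per-rater additive shifts; agreement is not.
    """
    mat = np.asarray(ratings, dtype=float)
    n, k = mat.shape
    if k < 2 or n < 5:
        raise ValueError("need >= 2 raters and >= 5 subjects")
    if np.isnan(mat).any():
        raise ValueError("ratings table must be complete")
    grand = mat.mean()
    row_means = mat.mean(axis=1)
    col_means = mat.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_tot = ((mat - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr == 0:
        raise DegenerateDataError("zero between-subject variance")
    if model == "consistency":
        est = (msr - mse) / (msr + (k - 1) * mse)
    elif model == "agreement":
        est = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    else:
        raise ValueError(f"unknown ICC model {model!r}")
    if mse == 0:
        f, p = math.inf, 0.0
    else:
        f = msr / mse
        p = sps.f.sf(f, n - 1, (n - 1) * (k - 1))
    return StatResult(f"icc_{model}", float(est), float("nan"), float(f),
                      float(n - 1), float(p), n,
                      notes=f"two-way single-rater, k={k}")
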