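"""Association analysis: adjusted regressions, residualized scores, FDR control.

The analysis contrasts two familial-risk indicators — the continuous familial
loading score (FLS) and the dichotomous family-history flag (FH) — as
predictors of continuous vulnerability outcomes.  For every outcome three
covariate-adjusted linear models are fitted (exposure = FLS; exposure = FH;
exposure = FLS residualized on FH, i.e. the component of familial loading
orthogonal to the dichotomy), and exposure p-values are corrected with the
Benjamini-Hochberg step-up procedure at a 5% false discovery rate.

Standardized coefficients follow the SPSS convention: beta = b * sd(x)/sd(y),
which equals the coefficient from refitting with every variable (including
binary ones) z-scored.  A partially-standardized alternative (binary exposure
left on its natural 0/1 scale) is available via ``standardize="partial"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

__all__ = [
    "AssociationResult",
    "ModelError",
    "AdjustedLinearModel",
    "aggregate_repeated_measures",
    "fit_adjusted",
    "residualize",
    "point_biserial",
    "pearson",
    "student_t",
    "chi_square_2x2",
    "bh_fdr",
    "run_full_analysis",
    "fls_distribution_summary",
    "DEFAULT_COVARIATES",
]

DEFAULT_COVARIATES = ("age", "gender", "education_years")


class ModelError(ValueError):
    """A regression model cannot be fitted (rank deficiency, constant exposure, ...)."""


@dataclass
class AssociationResult:
    """One exposure-outcome model row (coefficient-table shape)."""

    outcome: str
    exposure: str
    b: float
    ci_low: float
    ci_high: float
    beta: float
    p_raw: float
    n_used: int
    bh_reject: bool | None = None


def aggregate_repeated_measures(values_by_wave: Sequence[float]) -> float:
    """Mean over non-missing wave values; all-missing propagates as NaN."""
    arr = np.asarray(values_by_wave, dtype=float)
    if np.all(np.isnan(arr)):
        return float("nan")
    return float(np.nanmean(arr))


class AdjustedLinearModel(BaseEstimator):
    """OLS of an outcome on one exposure plus nuisance covariates.

    Parameters
    ----------
    exposure : column name of the predictor of interest.
    covariates : column names of adjustment variables (default age, gender,
        years of education).
    standardize : "full" (z-score everything, binary included; SPSS
        convention) or "partial" (exposure sd left at 1 when binary).

    Fitted attributes
    -----------------
    coef_ : unstandardized exposure coefficient b
    conf_int_ : 95% confidence interval of b
    beta_ : standardized exposure coefficient
    pvalue_ : two-sided p for the exposure term
    n_used_ : complete cases used
    results_ : the underlying statsmodels results object
    """

    def __init__(
        self,
        exposure: str = "fls",
        covariates: Sequence[str] = DEFAULT_COVARIATES,
        standardize: str = "full",
    ):
        self.exposure = exposure
        self.covariates = covariates
        self.standardize = standardize

    def fit(self, X: pd.DataFrame, y) -> "AdjustedLinearModel":
        if self.standardize not in ("full", "partial"):
            raise ValueError(f"unknown standardize convention {self.standardize!r}")
        y = pd.Series(np.asarray(y, dtype=float), index=X.index, name="_y")
        cols = [self.exposure, *self.covariates]
        data = pd.concat([X[cols].astype(float), y], axis=1).dropna()
        n = len(data)
        if n < 10:
            raise ModelError(f"only {n} complete cases (need >= 10)")
        x = data[self.exposure].to_numpy()
        if np.ptp(x) == 0:
            raise ModelError(f"exposure {self.exposure!r} is constant")
        design = sm.add_constant(data[cols])
        if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
            raise ModelError("design matrix is rank deficient")
        res = sm.OLS(data["_y"], design).fit()
        self.results_ = res
        self.coef_ = float(res.params[self.exposure])
        ci = res.conf_int(alpha=0.05).loc[self.exposure]
        self.conf_int_ = (float(ci[0]), float(ci[1]))
        self.pvalue_ = float(res.pvalues[self.exposure])
        sd_x, sd_y = data[self.exposure].std(ddof=1), data["_y"].std(ddof=1)
        binary = set(np.unique(x)) <= {0.0, 1.0}
        if self.standardize == "partial" and binary:
            self.beta_ = float(self.coef_ / sd_y)
        else:
            # equals the coefficient from refitting with all variables z-scored
            self.beta_ = float(self.coef_ * sd_x / sd_y)
        self.n_used_ = n
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "results_"):
            raise NotFittedError("AdjustedLinearModel is not fitted")
        design = sm.add_constant(X[[self.exposure, *self.covariates]].astype(float))
        return np.asarray(self.results_.predict(design))


def fit_adjusted(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    standardize: str = "full",
) -> AssociationResult:
    """Fit one covariate-adjusted model; thin wrapper over AdjustedLinearModel."""
    m = AdjustedLinearModel(exposure=exposure, covariates=covariates, standardize=standardize)
    m.fit(data, data[outcome])
    return AssociationResult(
        outcome=outcome,
        exposure=exposure,
        b=m.coef_,
        ci_low=m.conf_int_[0],
        ci_high=m.conf_int_[1],
        beta=m.beta_,
        p_raw=m.pvalue_,
        n_used=m.n_used_,
    )


def residualize(fls: Sequence[float], fh: Sequence[int]) -> np.ndarray:
    """Residuals of FLS regressed on FH (intercept included).

    The residualized score is the part of continuous familial loading
    orthogonal to the dichotomous indicator; by the OLS normal equations it
    has mean 0 and zero sample correlation with FH.
    """
    fls = np.asarray(fls, dtype=float)
    fh = np.asarray(fh, dtype=float)
    if np.unique(fh).size < 2:
        raise ModelError("fh must contain both levels to residualize on")
    design = sm.add_constant(fh)
    return np.asarray(sm.OLS(fls, design).fit().resid)


def point_biserial(binary: Sequence[int], continuous: Sequence[float]) -> float:
    """Point-biserial correlation: Pearson r with 0/1 numeric coding."""
    b = np.asarray(binary, dtype=float)
    if not set(np.unique(b)) <= {0.0, 1.0} or np.unique(b).size < 2:
        raise ModelError("binary variable must be 0/1 with both levels present")
    return pearson(b, continuous)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ModelError("need n >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ModelError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def student_t(group1: Sequence[float], group2: Sequence[float]) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test; df = n1 + n2 - 2.

    The pooled (Student) variant is used so that the degrees of freedom equal
    N - 2 for two groups partitioning a sample of size N.  The sign follows
    the group order (group1 mean minus group2 mean).
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ModelError("each group needs n >= 2")
    df = g1.size + g2.size - 2
    if np.ptp(g1) == 0 and np.ptp(g2) == 0 and g1.mean() != g2.mean():
        raise ModelError("zero pooled variance with unequal means (degenerate t)")
    res = stats.ttest_ind(g1, g2, equal_var=True)
    return float(res.statistic), int(df), float(res.pvalue)


def chi_square_2x2(counts) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table, WITHOUT Yates continuity correction."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("counts must be a 2x2 non-negative table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ModelError("chi-square undefined with a zero marginal")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def bh_fdr(p_values: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Sort p ascending, find the largest k with p_(k) <= k*q/m and reject the k
    smallest; adjusted p-values by the standard monotone cumulative minimum.
    Raw p-values are left untouched (reports keep the raw scale).

    Returns (reject flags, adjusted p) in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresholds = (np.arange(1, m + 1) / m) * q
    passing = np.nonzero(ranked <= thresholds)[0]
    reject = np.zeros(m, dtype=bool)
    if passing.size:
        reject[order[: passing[-1] + 1]] = True
    adj = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adj, 1.0)
    return reject, adjusted


def fls_distribution_summary(fls: Sequence[float], fh: Sequence[int]) -> dict:
    """Per-FH-group mean/sd of the FLS plus an empirical overlap coefficient.

    The overlap coefficient is the shared area of the two group histograms
    (40 equal-width bins over the pooled range, densities normalised to 1);
    1 means identical distributions, 0 means complete separation.
    """
    fls = np.asarray(fls, dtype=float)
    fh = np.asarray(fh, dtype=int)
    g0, g1 = fls[fh == 0], fls[fh == 1]
    bins = np.histogram_bin_edges(fls, bins=40)
    h0, _ = np.histogram(g0, bins=bins, density=False)
    h1, _ = np.histogram(g1, bins=bins, density=False)
    overlap = float(np.minimum(h0 / max(h0.sum(), 1), h1 / max(h1.sum(), 1)).sum())
    return {
        "fh_neg": {"n": int(g0.size), "mean": float(g0.mean()), "sd": float(g0.std(ddof=1))},
        "fh_pos": {"n": int(g1.size), "mean": float(g1.mean()), "sd": float(g1.std(ddof=1))},
        "overlap_coefficient": overlap,
    }


EXPOSURES = ("fls", "fh", "fls_resid")
RESERVED = {
    "proband_id", "age", "gender", "education_years", "true_liability",
    "affected", "fh", "fls", "fls_resid", "n_relatives", "n_affected", "prs",
}


def run_full_analysis(
    participants: pd.DataFrame,
    outcomes: Sequence[str] | None = None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    q: float = 0.05,
    bh_family: str = "per_exposure",
    standardize: str = "full",
) -> tuple[pd.DataFrame, dict]:
    """Full pipeline: three adjusted models per outcome + FDR + correlations.

    For every outcome, exposures FLS, FH and FH-residualized FLS are fitted
    with covariate adjustment.  ``bh_family`` controls the multiple-testing
    family: "per_exposure" (default) corrects across outcomes separately
    within each exposure block; "global" pools all exposure p-values into one
    family.

    Returns
    -------
    (results, summary)
        ``results`` is a coefficient table with one row per outcome-exposure
        pair (b, 95% CI, standardized beta, raw p, BH decision, n);
        ``summary`` holds the FH/FLS point-biserial correlation, FLS/PRS and
        FH/PRS correlations when a PRS column is present, the pooled t-test of
        FLS by FH group, and the per-group FLS distribution summary.
    """
    if bh_family not in ("per_exposure", "global"):
        raise ValueError(f"unknown bh_family {bh_family!r}")
    for col in ("fls", "fh", *covariates):
        if col not in participants.columns:
            raise ValueError(f"participant table lacks required column {col!r}")
    if outcomes is None:
        outcomes = [c for c in participants.columns if c not in RESERVED]
    if not outcomes:
        raise ValueError("no outcome columns to analyse")

    data = participants.copy()
    data["fls_resid"] = residualize(data["fls"], data["fh"])

    rows = [
        fit_adjusted(data, outcome, exposure, covariates, standardize=standardize)
        for exposure in EXPOSURES
        for outcome in outcomes
    ]
    results = pd.DataFrame([vars(r) for r in rows])

    if bh_family == "global":
        reject, adj = bh_fdr(results["p_raw"].to_numpy(), q)
        results["bh_reject"] = reject
        results["p_bh"] = adj
    else:
        results["p_bh"] = np.nan
        for exposure in EXPOSURES:
            mask = results["exposure"] == exposure
            reject, adj = bh_fdr(results.loc[mask, "p_raw"].to_numpy(), q)
            results.loc[mask, "bh_reject"] = reject
            results.loc[mask, "p_bh"] = adj
    results["bh_reject"] = results["bh_reject"].astype(bool)

    fh = data["fh"].to_numpy()
    fls = data["fls"].to_numpy()
    t, df, p_t = student_t(fls[fh == 0], fls[fh == 1])
    summary = {
        "r_fh_fls": point_biserial(fh, fls),
        "t_fls_by_fh": {"t": t, "df": df, "p": p_t},
        "fls_distribution": fls_distribution_summary(fls, fh),
        "n": int(len(data)),
    }
    if "prs" in data.columns:
        summary["r_fls_prs"] = pearson(fls, data["prs"])
        summary["r_fh_prs"] = point_biserial(fh, data["prs"])
    return results, summary
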