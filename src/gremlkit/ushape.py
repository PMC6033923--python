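"""Quadratic response-transform analysis of age at first birth (AFB).

Epidemiological registry data show a U-shaped relationship between maternal
age and schizophrenia risk in offspring: risk is elevated for both young and
old mothers.  That relationship is encoded as a fixed quadratic transform of
a woman's age at first birth,

    z = 2.7214 - 0.1105 * X + 0.0018 * X**2

(X in years; coefficients taken as given from the registry-derived model,
risk scale; minimum near X = 30.7).  Regressing z on a schizophrenia
polygenic risk score, with covariates, tests whether the U-shape is
partially explained by genetic overlap: a positive PRS coefficient means
genetically higher-risk women cluster at the extremes of AFB.

Because covariates explain most of the variance of z, the informative R²
is the *incremental* R² of the PRS term (full model minus covariate-only
model); both are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .greml import _drop_collinear

logger = logging.getLogger(__name__)

#: registry-derived polynomial coefficients (intercept, linear, quadratic)
RESPONSE_COEFFICIENTS = (2.7214, -0.1105, 0.0018)

#: AFB bin edges in years; bins are [0,20), [20,25), [25,30), [30,35), [35,inf)
AFB_BIN_EDGES = (0.0, 20.0, 25.0, 30.0, 35.0, np.inf)
AFB_BIN_LABELS = ("<20", "20-<25", "25-<30", "30-<35", ">=35")

#: default stratification cut-point in years (the cohort mean AFB, rounded)
DEFAULT_CUTPOINT = 26.0


def response_transform(afb: np.ndarray | float) -> np.ndarray | float:
    """Evaluate the quadratic risk transform at age(s) at first birth."""
    afb_arr = np.asarray(afb, dtype=float)
    if np.any(afb_arr < 0):
        raise ValueError("age at first birth must be non-negative")
    c0, c1, c2 = RESPONSE_COEFFICIENTS
    z = c0 + c1 * afb_arr + c2 * afb_arr**2
    return float(z) if np.isscalar(afb) else z


def response_minimum() -> float:
    """AFB (years) at which the transform is minimal: -c1 / (2 c2)."""
    _, c1, c2 = RESPONSE_COEFFICIENTS
    return -c1 / (2.0 * c2)


@dataclass
class ResponseRegressionResult:
    """PRS coefficient in the z-on-PRS multiple regression."""

    beta_prs: float
    se: float
    p: float                      # two-sided t-test on the PRS coefficient
    r_squared: float              # incremental R^2 of the PRS term
    r_squared_full: float         # full-model R^2, for reference
    n: int

    def summary(self) -> str:
        return (
            f"response ~ PRS + covariates  (n = {self.n})\n"
            f"  beta(PRS) = {self.beta_prs:.6g} (SE {self.se:.3g}), "
            f"p = {self.p:.3g}\n"
            f"  incremental R^2 = {self.r_squared:.3g} "
            f"(full model R^2 = {self.r_squared_full:.3g})"
        )


class ResponseRegression:
    """OLS of the transformed response on a PRS plus covariates.

    Complete cases only (listwise deletion, counts logged); collinear
    covariate columns are dropped with a warning.  ``fit()`` returns a
    :class:`ResponseRegressionResult`.
    """

    def __init__(
        self,
        z: np.ndarray,
        prs: np.ndarray,
        covariates: np.ndarray | None = None,
    ):
        z = np.asarray(z, dtype=float)
        prs = np.asarray(prs, dtype=float)
        if covariates is not None:
            covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
            if covariates.shape[0] != len(z):
                covariates = covariates.T
        complete = np.isfinite(z) & np.isfinite(prs)
        if covariates is not None:
            complete &= np.all(np.isfinite(covariates), axis=1)
        dropped = int((~complete).sum())
        if dropped:
            logger.info("listwise deletion removed %d incomplete cases", dropped)
        self.z = z[complete]
        self.prs = prs[complete]
        self.covariates = covariates[complete] if covariates is not None else None
        self.n = int(complete.sum())

    def fit(self) -> ResponseRegressionResult:
        cov_design = np.ones((self.n, 1))
        if self.covariates is not None:
            cov_design = _drop_collinear(
                np.column_stack([cov_design, self.covariates])
            )
        full_design = np.column_stack([cov_design, self.prs])
        if self.n <= full_design.shape[1]:
            raise ValueError("more parameters than observations")

        full = sm.OLS(self.z, full_design).fit()
        reduced = sm.OLS(self.z, cov_design).fit()
        k = full_design.shape[1] - 1  # PRS is the last column
        return ResponseRegressionResult(
            beta_prs=float(full.params[k]),
            se=float(full.bse[k]),
            p=float(full.pvalues[k]),
            r_squared=max(float(full.rsquared - reduced.rsquared), 0.0),
            r_squared_full=float(full.rsquared),
            n=self.n,
        )


def regress_response_on_prs(
    z: np.ndarray, prs: np.ndarray, covariates: np.ndarray | None = None
) -> ResponseRegressionResult:
    """Convenience wrapper: build and fit a :class:`ResponseRegression`."""
    return ResponseRegression(z, prs, covariates).fit()


def sensitivity_adjust(
    z: np.ndarray,
    prs: np.ndarray,
    covariates: np.ndarray | None,
    extra_covariates: np.ndarray,
    extra_names: list[str] | None = None,
) -> ResponseRegressionResult:
    """Re-fit the response regression with added lifestyle/SES covariates.

    Mirrors the sensitivity design in which education, income, smoking and
    alcohol status join the base covariates; samples missing any extra
    covariate drop out (shrinkage logged).  An all-missing extra covariate
    is an input error, not silently tolerated.
    """
    extra = np.atleast_2d(np.asarray(extra_covariates, dtype=float))
    if extra.shape[0] != len(z):
        extra = extra.T
    names = extra_names or [f"extra{i}" for i in range(extra.shape[1])]
    for j in range(extra.shape[1]):
        if np.all(~np.isfinite(extra[:, j])):
            raise ValueError(
                f"extra covariate {names[j]!r} has no observed values; "
                "drop it or supply data"
            )
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != len(z):
            covariates = covariates.T
        design = np.column_stack([covariates, extra])
    else:
        design = extra
    model = ResponseRegression(z, prs, design)
    logger.info("sensitivity model: n = %d after adding %s", model.n, names)
    return model.fit()


def stratify_by_afb(
    afb: np.ndarray, cutpoint: float | None = None
) -> np.ndarray:
    """Label each woman ``younger`` (AFB < cutpoint) or ``older`` (>= cutpoint).

    The default cut-point is the fixed integer 26 (the cohort-mean
    convention); pass ``cutpoint=None`` explicitly computed from your data
    if self-referential stratification is wanted.
    """
    afb = np.asarray(afb, dtype=float)
    cut = DEFAULT_CUTPOINT if cutpoint is None else float(cutpoint)
    labels = np.where(afb < cut, "younger", "older")
    for name in ("younger", "older"):
        if not (labels == name).any():
            logger.warning("empty stratum %r at cutpoint %g", name, cut)
    return labels


def bin_prs_by_afb(prs: np.ndarray, afb: np.ndarray) -> pd.DataFrame:
    """Mean (standardized) PRS per AFB bin with SE = sd/sqrt(n).

    Single-member bins have undefined SE, reported as NaN.
    """
    prs = np.asarray(prs, dtype=float)
    afb = np.asarray(afb, dtype=float)
    rows = []
    for lab, lo, hi in zip(AFB_BIN_LABELS, AFB_BIN_EDGES[:-1], AFB_BIN_EDGES[1:]):
        sel = (afb >= lo) & (afb < hi)
        vals = prs[sel]
        n = int(sel.sum())
        rows.append(
            {
                "bin": lab,
                "mean_prs": float(vals.mean()) if n else np.nan,
                "se": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                "n": n,
            }
        )
    return pd.DataFrame(rows)


def compare_bins(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Two-sided Welch t-test p-value between raw PRS values of two bins."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least two members")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return 1.0
        raise ValueError("degenerate variances with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)
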