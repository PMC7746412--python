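"""One-sample instrumental-variable estimation under additive structural
mean models.

The causal effect of an exposure X on an outcome Y is estimated by
two-stage least squares (2SLS) with a polygenic score Z as the single
instrument and nuisance covariates entering both stages as exogenous
regressors. The estimand is a mean difference for continuous outcomes and
a risk difference for binary outcomes, which are fitted as linear
probability models so that instrumented and ordinary estimates are directly
comparable.

Standard errors are heteroskedasticity-robust sandwich (HC1) estimates of
the IV estimator's variance, with residuals formed from the *observed*
exposure (not its first-stage fit). Weak-instrument strength is summarised
by the robust Wald F statistic of the instrument in the first stage (with a
single instrument this equals the Kleibergen–Paap rk Wald F), and the
endogeneity test is the control-function form of the Durbin–Wu–Hausman
test.

The model/results pair follows the usual statsmodels idiom::

    res = IVRegression(y, x, z, covariates=cov).fit()
    res.beta, res.se, res.f_statistic
    res.endogeneity_test()
    print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats, linalg

from .estimates import MREstimate, EndogeneityResult, Z_95
from .prs import PRSVector

__all__ = [
    "IVRegression", "IVRegressionResults",
    "fit_tsls", "first_stage_f", "endogeneity_test", "fit_adjusted",
    "covariate_design",
]


def covariate_design(cohort: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Expand a cohort covariate block into a numeric design.

    ``centre`` (recruitment centre codes) and any non-numeric column are
    one-hot encoded with the first level dropped; everything else passes
    through unchanged. No intercept column is added (the models add their
    own constant).
    """
    if columns is None:
        columns = [c for c in cohort.columns
                   if c in ("age", "sex", "centre") or c.startswith("pc")]
    out = {}
    for col in columns:
        s = cohort[col]
        if col == "centre" or not pd.api.types.is_numeric_dtype(s):
            dummies = pd.get_dummies(s.astype("category"), prefix=col,
                                     drop_first=True, dtype=float)
            for dc in dummies.columns:
                out[dc] = dummies[dc]
        else:
            out[col] = s.astype(float)
    return pd.DataFrame(out, index=cohort.index)


def _as_vector(v, name: str) -> np.ndarray:
    if isinstance(v, PRSVector):
        v = v.score
    arr = np.asarray(pd.Series(v).to_numpy(), dtype=float).ravel()
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


def _drop_collinear(M: np.ndarray, names: list) -> tuple:
    """Keep a maximal linearly independent column subset (QR with pivoting)."""
    if M.shape[1] == 0:
        return M, names
    _, r, piv = linalg.qr(M, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = M.shape[0] * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > max(tol, 1e-12)))
    if rank < M.shape[1]:
        keep = np.sort(piv[:rank])
        dropped = [names[j] for j in piv[rank:]]
        warnings.warn(f"dropping collinear covariate columns: {dropped}")
        return M[:, keep], [names[j] for j in keep]
    return M, names


def _assemble(outcome, exposure, instrument, covariates):
    """Positionally align inputs, expand covariates, drop incomplete rows."""
    y = _as_vector(outcome, "outcome")
    x = _as_vector(exposure, "exposure")
    parts = {"y": y, "x": x}
    if instrument is not None:
        parts["z"] = _as_vector(instrument, "instrument")
    lengths = {k: len(v) for k, v in parts.items()}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"input lengths differ: {lengths}")
    n = lengths["y"]

    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        if len(cov) != n:
            raise ValueError("covariates length differs from outcome length")
        if not all(pd.api.types.is_numeric_dtype(cov[c]) for c in cov.columns):
            cov = covariate_design(cov, list(cov.columns))
        C = cov.to_numpy(float)
        cov_names = list(cov.columns)
    else:
        C = np.empty((n, 0))
        cov_names = []

    mask = np.ones(n, dtype=bool)
    for v in parts.values():
        mask &= np.isfinite(v)
    if C.shape[1]:
        mask &= np.isfinite(C).all(axis=1)
    parts = {k: v[mask] for k, v in parts.items()}
    C = C[mask]
    n_used = int(mask.sum())
    if n_used < C.shape[1] + 4:
        raise ValueError(
            f"too few complete-case rows ({n_used}) for {C.shape[1]} covariates"
        )
    const = np.ones((n_used, 1))
    exog = np.column_stack([const, C])
    exog, kept = _drop_collinear(exog, ["const"] + cov_names)
    return parts, exog, kept


def _hc1_cov(design: np.ndarray, bread_mat: np.ndarray, resid: np.ndarray) -> np.ndarray:
    n, k = design.shape
    meat = (design * resid[:, None] ** 2).T @ design
    cov = bread_mat @ meat @ bread_mat
    return cov * n / (n - k)


def _residualize(v: np.ndarray, exog: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(exog, v, rcond=None)
    return v - exog @ coef


class IVRegression:
    """Two-stage least squares with one instrument and exogenous covariates.

    Parameters
    ----------
    outcome, exposure : array-like
        Aligned per-individual vectors. Binary variables are handled on the
        linear (probability) scale.
    instrument : array-like or PRSVector
        The polygenic score (or any single instrument).
    covariates : DataFrame, optional
        Exogenous covariates; enter both stages. Non-numeric columns and a
        ``centre`` column are expanded to indicators.

    Rows with any missing value among the used variables are dropped
    (complete-case), and the analysed n reflects that.
    """

    def __init__(self, outcome, exposure, instrument, covariates=None):
        parts, exog, cov_names = _assemble(outcome, exposure, instrument, covariates)
        self.y = parts["y"]
        self.x = parts["x"]
        self.z = parts["z"]
        self.exog = exog              # [const, covariates], full column rank
        self.cov_names = cov_names
        self.nobs = len(self.y)

    def fit(self) -> "IVRegressionResults":
        y, x, z, exog = self.y, self.x, self.z, self.exog
        n = self.nobs

        z_resid = _residualize(z, exog)
        x_resid = _residualize(x, exog)
        denom = float(z_resid @ x_resid)
        if np.sqrt(z_resid @ z_resid) < 1e-12 * max(1.0, np.sqrt(z @ z)):
            raise ValueError("instrument has no partial variance after covariates")
        if abs(denom) < 1e-12 * max(1.0, np.std(x) * np.std(z) * n):
            raise ValueError("zero first-stage coefficient: IV estimate is singular")

        # first stage: x on [exog, z]
        W = np.column_stack([exog, z])
        WtW_inv = np.linalg.inv(W.T @ W)
        fs_coef = WtW_inv @ (W.T @ x)
        x_hat = W @ fs_coef
        fs_resid = x - x_hat
        fs_cov = _hc1_cov(W, WtW_inv, fs_resid)
        g = fs_coef[-1]
        se_g = np.sqrt(fs_cov[-1, -1])
        f_stat = float((g / se_g) ** 2)

        # second stage on fitted exposure; sandwich uses observed-x residuals
        Rhat = np.column_stack([exog, x_hat])
        RtR_inv = np.linalg.inv(Rhat.T @ Rhat)
        coef = RtR_inv @ (Rhat.T @ y)
        R_obs = np.column_stack([exog, x])
        resid = y - R_obs @ coef
        vcov = _hc1_cov(Rhat, RtR_inv, resid)

        return IVRegressionResults(
            model=self,
            params=coef,
            vcov=vcov,
            param_names=self.cov_names + ["exposure"],
            f_statistic=f_stat,
            f_df=(1, n - W.shape[1]),
            first_stage_coef=fs_coef,
            first_stage_resid=fs_resid,
            resid=resid,
        )


@dataclass
class IVRegressionResults:
    """Fitted 2SLS results: estimate, robust inference and diagnostics."""

    model: IVRegression
    params: np.ndarray
    vcov: np.ndarray
    param_names: list
    f_statistic: float
    f_df: tuple
    first_stage_coef: np.ndarray
    first_stage_resid: np.ndarray
    resid: np.ndarray

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def beta(self) -> float:
        """Causal effect of the (instrumented) exposure."""
        return float(self.params[-1])

    @property
    def se(self) -> float:
        return float(np.sqrt(self.vcov[-1, -1]))

    @property
    def pvalue(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.beta / self.se)))

    def conf_int(self) -> tuple:
        return (self.beta - Z_95 * self.se, self.beta + Z_95 * self.se)

    def endogeneity_test(self) -> EndogeneityResult:
        """Control-function Durbin–Wu–Hausman test.

        The first-stage residual is added to the outcome regression on the
        observed exposure and covariates; a robust Wald test on its
        coefficient compares the IV and ordinary estimates.
        """
        v = self.first_stage_resid
        scale = np.std(self.model.x)
        if np.max(np.abs(v)) <= 1e-12 * max(1.0, scale):
            raise ValueError(
                "exposure has no endogenous variation (first-stage residual "
                "is identically zero); endogeneity test undefined"
            )
        D = np.column_stack([self.model.exog, self.model.x, v])
        DtD_inv = np.linalg.inv(D.T @ D)
        coef = DtD_inv @ (D.T @ self.model.y)
        resid = self.model.y - D @ coef
        cov = _hc1_cov(D, DtD_inv, resid)
        t2 = float(coef[-1] ** 2 / cov[-1, -1])
        return EndogeneityResult(statistic=t2, p=float(stats.chi2.sf(t2, 1)), df=1)

    def to_estimate(self, method: str = "MR (2SLS)") -> MREstimate:
        lo, hi = self.conf_int()
        return MREstimate(
            beta=self.beta, se=self.se, ci_low=lo, ci_high=hi,
            p=self.pvalue, n=self.nobs, method=method, f_stat=self.f_statistic,
        )

    def summary(self) -> str:
        lo, hi = self.conf_int()
        lines = [
            "One-sample Mendelian randomization (2SLS, robust SE)",
            "=" * 56,
            f"{'n (complete case)':<28}{self.nobs:>12d}",
            f"{'causal effect':<28}{self.beta:>12.4f}",
            f"{'robust SE (HC1)':<28}{self.se:>12.4f}",
            f"{'95% CI':<28}[{lo:>10.4f}, {hi:>10.4f}]",
            f"{'p-value':<28}{self.pvalue:>12.3g}",
            f"{'first-stage robust F':<28}{self.f_statistic:>12.1f}",
            "=" * 56,
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional surface

def fit_tsls(exposure, outcome, instrument, covariates=None,
             method: str = "MR (2SLS)") -> MREstimate:
    """Two-stage least squares causal estimate (see :class:`IVRegression`)."""
    return IVRegression(outcome, exposure, instrument, covariates).fit() \
        .to_estimate(method=method)


def first_stage_f(exposure, instrument, covariates=None) -> tuple:
    """Robust Wald F for the instrument in the first-stage regression.

    Returns ``(F, (df1, df2))``. With one instrument this equals the
    Kleibergen–Paap rk Wald F reported by ivreg-style software.
    """
    parts, exog, _ = _assemble(exposure, exposure, instrument, covariates)
    x, z = parts["y"], parts["z"]
    W = np.column_stack([exog, z])
    WtW_inv = np.linalg.inv(W.T @ W)
    coef = WtW_inv @ (W.T @ x)
    resid = x - W @ coef
    cov = _hc1_cov(W, WtW_inv, resid)
    f = float(coef[-1] ** 2 / cov[-1, -1])
    return f, (1, len(x) - W.shape[1])


def endogeneity_test(exposure, outcome, instrument, covariates=None) -> EndogeneityResult:
    """Durbin–Wu–Hausman endogeneity test (control-function form)."""
    return IVRegression(outcome, exposure, instrument, covariates).fit() \
        .endogeneity_test()


def fit_adjusted(exposure, outcome, covariates=None,
                 method: str = "multivariable-adjusted") -> MREstimate:
    """Ordinary multivariable-adjusted association with robust (HC1) SEs.

    The non-genetic comparator: OLS of the outcome on the exposure and
    covariates, a linear probability model when the outcome is binary, so
    units match :func:`fit_tsls` for side-by-side display.
    """
    import statsmodels.api as sm

    parts, exog, _ = _assemble(outcome, exposure, None, covariates)
    y, x = parts["y"], parts["x"]
    design = np.column_stack([exog, x])
    res = sm.OLS(y, design).fit(cov_type="HC1")
    beta, se = float(res.params[-1]), float(res.bse[-1])
    return MREstimate.from_beta_se(beta, se, n=len(y), method=method)
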