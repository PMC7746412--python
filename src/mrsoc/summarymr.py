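"""Per-variant association (the GWAS stage) and summary-statistic
sensitivity estimators for pleiotropy-robust Mendelian randomization.

The sensitivity suite operates on per-variant summary statistics (SNP→
exposure and SNP→outcome associations with standard errors):

* **Wald ratios** — per-variant causal estimates ``beta_out / beta_exp``
  with first-order standard errors ``|se_out / beta_exp|`` (exposure-side
  uncertainty ignored, the NOME approximation);
* **IVW** — fixed-effect inverse-variance-weighted regression of outcome
  on exposure associations through the origin, with Cochran's Q as the
  heterogeneity diagnostic;
* **MR-Egger** — the same weighted regression with an intercept; a nonzero
  intercept indicates directional pleiotropy. SEs are scaled by
  max(1, sigma) and p-values use t with k−2 df (robust to overdispersion);
* **weighted median** — consistent when ≥50% of the weight is on valid
  instruments; SE by seeded parametric bootstrap;
* **mode-based estimators** (simple and weighted) — consistent when the
  largest group of variants shares the true ratio; kernel-density mode with
  a MAD-based bandwidth, SE by seeded parametric bootstrap.

Estimators requiring spread in the ratios are only defined for three or
more variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats, optimize

from .estimates import MREstimate
from .prs import GenotypeMatrix

__all__ = [
    "SUMMARY_COLUMNS", "QResult", "EggerResult",
    "per_snp_assoc", "select_gws", "wald_ratios",
    "ivw", "egger", "weighted_median", "mode_estimators",
    "read_summary_stats", "write_summary_stats",
]

SUMMARY_COLUMNS = ["snp", "beta_exp", "se_exp", "pval_exp", "beta_out", "se_out", "n"]

_SE_FLOOR = 1e-12  # reported in place of an exactly-zero bootstrap SE


@dataclass
class QResult:
    """Cochran's Q heterogeneity statistic from the IVW fit."""

    q: float
    df: int
    p: float

    def __post_init__(self) -> None:
        if self.q < 0:
            raise ValueError("Q must be non-negative")


@dataclass
class EggerResult:
    """MR-Egger fit: causal slope plus the directional-pleiotropy intercept."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_p: float
    intercept_ci_low: float
    intercept_ci_high: float
    df: int


# ---------------------------------------------------------------------------
# GWAS stage

def per_snp_assoc(genotypes: GenotypeMatrix, trait, covariates=None) -> pd.DataFrame:
    """Per-variant linear association of a trait with allele dosage.

    Each variant is regressed on the trait jointly with the covariates
    (equivalently: both sides are residualized on the covariates first).
    Binary traits are analysed with the same linear model, keeping effects
    on the risk-difference scale. Monomorphic variants are flagged with an
    undefined beta rather than dropped.
    """
    t = np.asarray(pd.Series(trait).to_numpy(), dtype=float).ravel()
    n = genotypes.n_individuals
    if len(t) != n:
        raise ValueError("trait length does not match genotype rows")
    if covariates is not None:
        C = pd.DataFrame(covariates).reset_index(drop=True).to_numpy(float)
        if len(C) != n:
            raise ValueError("covariate rows do not match genotype rows")
    else:
        C = np.empty((n, 0))

    mask = np.isfinite(t)
    if C.shape[1]:
        mask &= np.isfinite(C).all(axis=1)
    G = genotypes.dosages[mask]
    t = t[mask]
    Q = np.column_stack([np.ones(mask.sum()), C[mask]])
    if np.ptp(t) == 0:
        raise ValueError("trait is constant; association undefined")

    QtQ_inv = np.linalg.pinv(Q.T @ Q)
    proj = lambda M: M - Q @ (QtQ_inv @ (Q.T @ M))
    t_r = proj(t)
    if np.isnan(G).any():
        # per-variant pairwise-complete fallback
        betas, ses, ps = [], [], []
        for j in range(G.shape[1]):
            gj = G[:, j]
            mj = np.isfinite(gj)
            res = _single_assoc(t[mj], gj[mj], Q[mj])
            betas.append(res[0]); ses.append(res[1]); ps.append(res[2])
        beta, se, p = map(np.asarray, (betas, ses, ps))
    else:
        G_r = proj(G)
        sxx = np.einsum("ij,ij->j", G_r, G_r)
        sxy = G_r.T @ t_r
        styy = float(t_r @ t_r)
        dof = len(t) - Q.shape[1] - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = sxy / sxx
            rss = styy - beta ** 2 * sxx
            se = np.sqrt(np.maximum(rss, 0.0) / dof / sxx)
            p = 2.0 * stats.t.sf(np.abs(beta / se), dof)
        zero = sxx <= 1e-12
        beta[zero] = np.nan
        se[zero] = np.nan
        p[zero] = np.nan

    out = pd.DataFrame({
        "snp": genotypes.variants["snp"].to_numpy(),
        "beta": beta, "se": se, "pval": p,
        "n": int(mask.sum()),
        "monomorphic": ~np.isfinite(beta),
    })
    return out


def _single_assoc(t, g, Q):
    if np.ptp(g) == 0:
        return np.nan, np.nan, np.nan
    X = np.column_stack([Q, g])
    coef, _, rank, _ = np.linalg.lstsq(X, t, rcond=None)
    resid = t - X @ coef
    dof = len(t) - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    se = np.sqrt(cov[-1, -1])
    p = 2.0 * stats.t.sf(abs(coef[-1] / se), dof)
    return float(coef[-1]), float(se), float(p)


def select_gws(stats_df: pd.DataFrame, threshold: float = 5e-8,
               p_column: str = None) -> pd.DataFrame:
    """Keep variants reaching the significance threshold, order preserved.

    The default threshold is conventional genome-wide significance
    (5 × 10⁻⁸). An empty result is legitimate (a trait may yield no
    significant variants in a split) and is returned, not raised.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if p_column is None:
        p_column = "pval_exp" if "pval_exp" in stats_df.columns else "pval"
    kept = stats_df[stats_df[p_column] <= threshold].reset_index(drop=True)
    return kept


# ---------------------------------------------------------------------------
# sensitivity estimators

def _unpack(stats_df: pd.DataFrame, min_variants: int):
    bx = stats_df["beta_exp"].to_numpy(float)
    by = stats_df["beta_out"].to_numpy(float)
    sy = stats_df["se_out"].to_numpy(float)
    sx = stats_df["se_exp"].to_numpy(float) if "se_exp" in stats_df.columns \
        else np.zeros_like(bx)
    sx = np.where(np.isfinite(sx), sx, 0.0)
    if np.any(~np.isfinite(bx) | ~np.isfinite(by) | ~np.isfinite(sy)):
        raise ValueError("non-finite summary statistics")
    if np.any(sy <= 0):
        raise ValueError("outcome standard errors must be positive")
    if len(bx) < min_variants:
        raise ValueError(f"at least {min_variants} variants required, got {len(bx)}")
    return bx, by, sx, sy


def _sample_n(stats_df: pd.DataFrame) -> int:
    if "n" in stats_df.columns and stats_df["n"].notna().any():
        return int(stats_df["n"].max())
    return len(stats_df)


def wald_ratios(stats_df: pd.DataFrame) -> pd.DataFrame:
    """Per-variant ratio estimates beta_out/beta_exp with first-order SEs.

    Exposure-side uncertainty is ignored (NOME approximation), so
    ``se = |se_out / beta_exp|``. Variants with a zero exposure association
    are excluded with a warning — their ratio is undefined.
    """
    bx, by, _, sy = _unpack(stats_df, 1)
    keep = bx != 0
    if not keep.all():
        dropped = stats_df.loc[~keep, "snp"].tolist()
        warnings.warn(f"excluding variants with zero exposure beta: {dropped}")
    out = stats_df.loc[keep, ["snp"]].copy()
    out["ratio"] = by[keep] / bx[keep]
    out["se"] = np.abs(sy[keep] / bx[keep])
    return out.reset_index(drop=True)


def ivw(stats_df: pd.DataFrame) -> tuple:
    """Fixed-effect inverse-variance-weighted estimate with Cochran's Q.

    Weighted regression of outcome associations on exposure associations
    through the origin (weights ``1/se_out²``); Q is the weighted residual
    sum of squares with k−1 degrees of freedom.
    """
    bx, by, _, sy = _unpack(stats_df, 2)
    w = 1.0 / sy ** 2
    swxx = float(np.sum(w * bx * bx))
    if swxx <= 0:
        raise ValueError("all exposure betas are zero; IVW undefined")
    beta = float(np.sum(w * bx * by) / swxx)
    se = float(np.sqrt(1.0 / swxx))
    q = float(np.sum(w * (by - beta * bx) ** 2))
    df = len(bx) - 1
    est = MREstimate.from_beta_se(beta, se, n=_sample_n(stats_df), method="IVW")
    return est, QResult(q=q, df=df, p=float(stats.chi2.sf(q, df)))


def egger(stats_df: pd.DataFrame) -> EggerResult:
    """MR-Egger: weighted regression with an intercept.

    Variants are re-oriented so every exposure association is positive
    (required for the intercept to be interpretable as average directional
    pleiotropy); exact zero exposure betas are excluded. SEs are scaled by
    max(1, sigma) — never deflated below the fixed-effect value — and
    inference uses t with k−2 df.
    """
    bx, by, _, sy = _unpack(stats_df, 3)
    keep = bx != 0
    bx, by, sy = bx[keep], by[keep], sy[keep]
    if len(bx) < 3:
        raise ValueError("fewer than 3 usable variants for MR-Egger")
    flip = np.sign(bx)
    bx, by = bx * flip, by * flip

    w = 1.0 / sy ** 2
    X = np.column_stack([np.ones_like(bx), bx])
    XtWX = X.T @ (w[:, None] * X)
    cov_unscaled = np.linalg.inv(XtWX)
    coef = cov_unscaled @ (X.T @ (w * by))
    resid = by - X @ coef
    df = len(bx) - 2
    sigma2 = float(np.sum(w * resid ** 2) / df)
    scale = max(1.0, np.sqrt(sigma2))
    se = np.sqrt(np.diag(cov_unscaled)) * scale
    tq = stats.t.ppf(0.975, df)
    pvals = 2.0 * stats.t.sf(np.abs(coef / se), df)

    slope = MREstimate(
        beta=float(coef[1]), se=float(se[1]),
        ci_low=float(coef[1] - tq * se[1]), ci_high=float(coef[1] + tq * se[1]),
        p=float(pvals[1]), n=_sample_n(stats_df), method="MR-Egger",
    )
    return EggerResult(
        slope=slope,
        intercept=float(coef[0]), intercept_se=float(se[0]),
        intercept_p=float(pvals[0]),
        intercept_ci_low=float(coef[0] - tq * se[0]),
        intercept_ci_high=float(coef[0] + tq * se[0]),
        df=df,
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, cum, v))


def weighted_median(stats_df: pd.DataFrame, n_boot: int = 1000,
                    seed: int = None) -> MREstimate:
    """Weighted-median estimator over per-variant Wald ratios.

    Ratios are ordered and the inverse-variance-weighted 50% point is found
    by linear interpolation of the standardized cumulative weights; valid
    if at least half the weight is on valid instruments. The SE comes from
    a seeded parametric bootstrap resampling both association vectors from
    their normal sampling distributions.
    """
    if seed is None:
        raise ValueError("a bootstrap seed is required for reproducibility")
    bx, by, sx, sy = _unpack(stats_df, 3)
    if np.any(bx == 0):
        raise ValueError("zero exposure beta; compute ratios on filtered stats")
    est = _weighted_median(by / bx, (bx / sy) ** 2)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = bx + sx * rng.standard_normal(len(bx))
        bys = by + sy * rng.standard_normal(len(by))
        bxs = np.where(bxs == 0, _SE_FLOOR, bxs)
        boots[b] = _weighted_median(bys / bxs, (bxs / sy) ** 2)
    se = max(float(np.std(boots, ddof=1)), _SE_FLOOR)
    return MREstimate.from_beta_se(est, se, n=_sample_n(stats_df),
                                   method="weighted median")


def _kde_mode(values: np.ndarray, weights: np.ndarray, h: float,
              refine: bool = True) -> float:
    lo, hi = values.min() - 3 * h, values.max() + 3 * h
    grid = np.linspace(lo, hi, 512)
    dens = np.exp(-0.5 * ((grid[:, None] - values[None, :]) / h) ** 2) @ weights
    j = int(np.argmax(dens))
    if not refine:
        return float(grid[j])
    a, b = grid[max(j - 1, 0)], grid[min(j + 1, len(grid) - 1)]

    def neg_density(x):
        return -float(np.exp(-0.5 * ((x - values) / h) ** 2) @ weights)

    res = optimize.minimize_scalar(neg_density, bounds=(a, b), method="bounded")
    return float(res.x)


def _mode_bandwidth(values: np.ndarray, bandwidth_factor: float) -> float:
    k = len(values)
    sd = float(np.std(values, ddof=1))
    mad = float(stats.median_abs_deviation(values, scale="normal"))
    s = min(x for x in (sd, mad) if x > 0) if (sd > 0 or mad > 0) else 0.0
    return bandwidth_factor * 0.9 * s * k ** (-1 / 5)


def mode_estimators(stats_df: pd.DataFrame, bandwidth_factor: float = 1.0,
                    n_boot: int = 1000, seed: int = None) -> tuple:
    """Simple- and weighted-mode estimates of the causal effect.

    The mode of a normal-kernel density over the Wald ratios; the weighted
    variant weights each ratio by its inverse variance. Bandwidth is
    ``bandwidth_factor`` times a MAD-based scale (0.9·min(SD, MADn)·k^(−1/5)).
    If all ratios are identical the common value is returned with a zero
    (floored) SE. SEs otherwise come from a seeded parametric bootstrap.
    """
    if seed is None:
        raise ValueError("a bootstrap seed is required for reproducibility")
    if bandwidth_factor <= 0:
        raise ValueError("bandwidth_factor must be positive")
    bx, by, sx, sy = _unpack(stats_df, 3)
    if np.any(bx == 0):
        raise ValueError("zero exposure beta; compute ratios on filtered stats")
    ratios = by / bx
    se_r = np.abs(sy / bx)
    w_simple = np.ones_like(ratios)
    w_weighted = 1.0 / se_r ** 2

    def point(r, ws):
        h = _mode_bandwidth(r, bandwidth_factor)
        if h == 0 or np.ptp(r) == 0:
            return float(r[0])
        return _kde_mode(r, ws / ws.sum(), h)

    est_simple = point(ratios, w_simple)
    est_weighted = point(ratios, w_weighted)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, 2))
    for b in range(n_boot):
        bxs = bx + sx * rng.standard_normal(len(bx))
        bys = by + sy * rng.standard_normal(len(by))
        bxs = np.where(bxs == 0, _SE_FLOOR, bxs)
        r = bys / bxs
        sr = np.abs(sy / bxs)
        h = _mode_bandwidth(r, bandwidth_factor)
        if h == 0 or np.ptp(r) == 0:
            boots[b] = (r[0], r[0])
            continue
        boots[b, 0] = _kde_mode(r, w_simple / w_simple.sum(), h, refine=False)
        ww = 1.0 / sr ** 2
        boots[b, 1] = _kde_mode(r, ww / ww.sum(), h, refine=False)
    se_s = max(float(np.std(boots[:, 0], ddof=1)), _SE_FLOOR)
    se_w = max(float(np.std(boots[:, 1], ddof=1)), _SE_FLOOR)
    n = _sample_n(stats_df)
    return (
        MREstimate.from_beta_se(est_simple, se_s, n=n, method="simple mode"),
        MREstimate.from_beta_se(est_weighted, se_w, n=n, method="weighted mode"),
    )


# ---------------------------------------------------------------------------
# text IO

def read_summary_stats(path_or_buf) -> pd.DataFrame:
    df = pd.read_csv(path_or_buf, sep="\t")
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns and c != "pval_exp"]
    if missing:
        raise ValueError(f"summary stats missing columns: {missing}")
    return df


def write_summary_stats(df: pd.DataFrame, path) -> None:
    cols = [c for c in SUMMARY_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)
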