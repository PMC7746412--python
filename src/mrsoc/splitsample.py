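"""Split-sample design: discover instruments in one half of the cohort,
estimate in the other, and combine with fixed-effect meta-analysis.

Splitting removes sample overlap between the GWAS that produces the score
weights and the individuals the score is evaluated on, which would
otherwise bias the IV estimate toward the confounded observational
association. The unit of randomization is the individual id (sorted, then
shuffled with a seeded generator), so the partition is reproducible and
independent of row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .estimates import MREstimate, MetaResult, Z_95
from .prs import GenotypeMatrix, compute_prs
from .onesample import fit_tsls
from .summarymr import per_snp_assoc, select_gws

__all__ = ["split_cohort", "fixed_effect_meta", "run_split_mr",
           "SplitHalf", "SplitResult"]


def split_cohort(ids, seed: int) -> Tuple[np.ndarray, np.ndarray]:
    """Seeded random partition of individual ids into two halves.

    Ids are sorted before shuffling so the partition depends only on the id
    set and the seed, not on input order. Sizes differ by at most one.
    """
    if isinstance(ids, pd.DataFrame):
        ids = ids["iid"]
    ids = np.sort(np.asarray(ids))
    if len(ids) != len(np.unique(ids)):
        raise ValueError("duplicate individual ids")
    n = len(ids)
    if n < 4:
        raise ValueError(f"need at least 4 individuals to split, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    half = (n + 1) // 2
    return ids[perm[:half]], ids[perm[half:]]


def fixed_effect_meta(estimates: Sequence) -> MetaResult:
    """Inverse-variance fixed-effect combination of two or more estimates.

    beta = Σ(bᵢ/seᵢ²)/Σ(1/seᵢ²); se = (Σ 1/seᵢ²)^(−1/2); normal CI and
    two-sided p. The combined SE is necessarily no larger than any input SE.
    """
    if len(estimates) < 2:
        raise ValueError("fixed-effect meta-analysis needs at least 2 estimates")
    betas = np.array([e.beta for e in estimates], dtype=float)
    ses = np.array([e.se for e in estimates], dtype=float)
    if np.any(ses <= 0):
        raise ValueError("all input SEs must be positive")
    w = 1.0 / ses ** 2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return MetaResult(beta=beta, se=se, ci_low=beta - Z_95 * se,
                      ci_high=beta + Z_95 * se, p=p)


@dataclass
class SplitHalf:
    """One half's contribution: instrument discovery count and MR estimate."""

    label: str
    ids: np.ndarray
    n_selected: int
    estimate: Optional[MREstimate] = None
    note: str = ""

    @property
    def estimable(self) -> bool:
        return self.estimate is not None


@dataclass
class SplitResult:
    """Both halves plus the fixed-effect combination (when estimable)."""

    halves: List[SplitHalf] = field(default_factory=list)
    combined: Optional[MetaResult] = None

    @property
    def estimable(self) -> bool:
        return self.combined is not None

    def summary(self) -> str:
        lines = ["Split-sample Mendelian randomization", "=" * 52]
        for h in self.halves:
            if h.estimable:
                e = h.estimate
                lines.append(
                    f"{h.label:<10} k={h.n_selected:<4d} beta={e.beta:+.4f} "
                    f"se={e.se:.4f} F={e.f_stat:.1f}"
                )
            else:
                lines.append(f"{h.label:<10} k={h.n_selected:<4d} not estimable"
                             f" ({h.note})")
        if self.combined is not None:
            c = self.combined
            lines.append(
                f"{'combined':<10} beta={c.beta:+.4f} se={c.se:.4f} "
                f"[{c.ci_low:+.4f}, {c.ci_high:+.4f}] p={c.p:.3g}"
            )
        else:
            lines.append("combined   not estimable")
        return "\n".join(lines)


def run_split_mr(
    genotypes: GenotypeMatrix,
    cohort: pd.DataFrame,
    exposure: str = "exposure",
    outcome: str = "outcome",
    covariates=None,
    gws_threshold: float = 5e-8,
    seed: int = 0,
) -> SplitResult:
    """The full split-sample analysis on one cohort.

    The cohort is halved at random; each half's GWAS of the exposure
    (covariate-adjusted per-variant regression, genome-wide threshold
    ``gws_threshold``) supplies score weights applied to the *other* half,
    so no individual contributes to both weight discovery and estimation.
    2SLS runs in each half with its cross-derived score and the two
    estimates are combined by fixed-effect meta-analysis. A half whose
    discovery GWAS selects no variants is reported as not estimable; if
    both halves are empty no combined estimate is produced (this is the
    expected behaviour for traits with no detectable common-variant
    signal).
    """
    cohort = cohort.reset_index(drop=True)
    if covariates is not None:
        covariates = pd.DataFrame(covariates).reset_index(drop=True)
    ids_a, ids_b = split_cohort(cohort["iid"].to_numpy(), seed=seed)

    pos = pd.Series(np.arange(len(cohort)), index=cohort["iid"])
    result = SplitResult()
    for est_label, disc_ids, est_ids in (("split A", ids_b, ids_a),
                                         ("split B", ids_a, ids_b)):
        disc_idx = pos.loc[disc_ids].to_numpy()
        est_idx = pos.loc[est_ids].to_numpy()
        geno_disc = genotypes.subset_individuals(cohort["iid"].iloc[disc_idx])
        cov_disc = covariates.iloc[disc_idx] if covariates is not None else None
        gwas = per_snp_assoc(geno_disc, cohort[exposure].iloc[disc_idx],
                             covariates=cov_disc)
        gwas = gwas[~gwas["monomorphic"]]
        selected = select_gws(gwas, threshold=gws_threshold, p_column="pval")
        half = SplitHalf(label=est_label, ids=np.asarray(est_ids),
                         n_selected=len(selected))
        if len(selected) == 0:
            half.note = "no variants reached the significance threshold"
            result.halves.append(half)
            continue
        panel = genotypes.variants.set_index("snp")
        weights = pd.DataFrame({
            "snp": selected["snp"],
            "effect_allele": panel.loc[selected["snp"], "counted_allele"].to_numpy(),
            "other_allele": panel.loc[selected["snp"], "other_allele"].to_numpy(),
            "beta": selected["beta"].to_numpy(),
            "se": selected["se"].to_numpy(),
            "pval": selected["pval"].to_numpy(),
        })
        geno_est = genotypes.subset_individuals(cohort["iid"].iloc[est_idx])
        prs = compute_prs(geno_est, weights)
        cov_est = covariates.iloc[est_idx] if covariates is not None else None
        half.estimate = fit_tsls(
            cohort[exposure].iloc[est_idx], cohort[outcome].iloc[est_idx],
            prs, covariates=cov_est, method=f"MR (2SLS, {est_label})",
        )
        result.halves.append(half)

    estimable = [h.estimate for h in result.halves if h.estimable]
    if len(estimable) == 2:
        result.combined = fixed_effect_meta(estimable)
    return result
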