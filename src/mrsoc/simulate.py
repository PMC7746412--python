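"""Synthetic genotype–phenotype cohorts for instrument-based causal inference.

The generator emulates the statistical structure that a one-sample Mendelian
randomization analysis of a biobank cohort assumes:

* biallelic SNPs in Hardy–Weinberg equilibrium, simulated independently
  (no LD — real analyses use GWAS-significant, clumped loci, so independent
  instruments are the intended regime);
* a continuous exposure built from per-allele genetic effects, a shared
  standard-normal confounder and Gaussian noise, optionally dichotomized by
  a liability threshold at a target prevalence;
* a continuous or binary outcome that responds to the exposure through a
  configurable causal effect, to the confounder, and — optionally — to the
  SNPs directly (horizontal pleiotropy, balanced or directional);
* nuisance covariates (age, sex, recruitment centre, genetic principal
  components) with small nonzero effects so covariate adjustment is
  non-trivial downstream.

Ground truth (per-SNP effects, pleiotropy, causal effect, confounder
loadings) is returned alongside the data so parameter-recovery tests can
compare estimates against what was actually drawn.

All randomness flows from a single ``numpy.random.default_rng(seed)``
(PCG64) stream, with draws made in a fixed documented order, so a given
config is byte-identical across runs and platforms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

import numpy as np
import pandas as pd

from .prs import GenotypeMatrix

_NUCLEOTIDES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CovariateSpec:
    """Shape of the simulated nuisance covariates.

    Defaults mirror a middle-aged population cohort: recruitment age 39–72,
    a roughly balanced sex ratio, a handful of assessment centres and a
    small number of standard-normal genetic principal components.
    """

    age_range: Tuple[float, float] = (39.0, 72.0)
    male_fraction: float = 0.46
    n_centres: int = 5
    n_pcs: int = 4

    def validate(self) -> None:
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be (low, high) with low < high")
        if not 0.0 < self.male_fraction < 1.0:
            raise ValueError("male_fraction must be in (0, 1)")
        if self.n_centres < 1 or self.n_pcs < 0:
            raise ValueError("n_centres must be >= 1 and n_pcs >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Settings for one synthetic cohort.

    ``snp_effect_scale`` is the standard deviation of the per-allele SNP
    effects on the exposure (effects are drawn N(0, scale²), giving a
    GWAS-like spread of instrument strengths). ``pleiotropy_mode`` selects
    direct SNP→outcome effects: ``"none"``, ``"balanced"`` (zero-mean,
    SD = ``pleiotropy_scale``) or ``"directional"`` (every SNP's outcome
    effect shifted by the constant ``pleiotropy_scale``).
    """

    seed: int
    n_individuals: int = 10_000
    n_snps: int = 30
    maf_range: Tuple[float, float] = (0.05, 0.5)
    snp_effect_scale: float = 0.1
    exposure_kind: str = "continuous"          # or "binary"
    prevalence: float = 0.1                    # binary exposures only
    causal_effect: float = 0.5
    confounder_effect_x: float = 0.5
    confounder_effect_y: float = 0.5
    pleiotropy_mode: str = "none"              # none | balanced | directional
    pleiotropy_scale: float = 0.0
    outcome_kind: str = "continuous"           # or "binary"
    outcome_prevalence: float = 0.1            # binary outcomes only
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)
    noise_sd_x: float = 1.0
    noise_sd_y: float = 1.0
    rng_algorithm: str = "PCG64"               # metadata: generator used

    def validate(self) -> None:
        if self.n_individuals <= 0 or self.n_snps <= 0:
            raise ValueError("n_individuals and n_snps must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name, prev in (("prevalence", self.prevalence),
                           ("outcome_prevalence", self.outcome_prevalence)):
            if not 0.0 < prev < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.exposure_kind not in ("continuous", "binary"):
            raise ValueError(f"unknown exposure_kind {self.exposure_kind!r}")
        if self.outcome_kind not in ("continuous", "binary"):
            raise ValueError(f"unknown outcome_kind {self.outcome_kind!r}")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.noise_sd_x < 0 or self.noise_sd_y < 0:
            raise ValueError("noise SDs must be non-negative")
        self.covariate_spec.validate()


@dataclass
class TrueParams:
    """Ground truth recorded exactly as drawn, for recovery tests."""

    maf: np.ndarray
    snp_effects_exposure: np.ndarray
    snp_effects_outcome: np.ndarray   # pleiotropic (direct) effects
    causal_effect: float
    confounder_effect_x: float
    confounder_effect_y: float
    covariate_effects_x: dict = field(default_factory=dict)
    covariate_effects_y: dict = field(default_factory=dict)

    def write(self, path) -> None:
        """Plain key-value text dump."""
        with open(path, "w") as fh:
            fh.write(f"causal_effect\t{self.causal_effect!r}\n")
            fh.write(f"confounder_effect_x\t{self.confounder_effect_x!r}\n")
            fh.write(f"confounder_effect_y\t{self.confounder_effect_y!r}\n")
            for j in range(len(self.maf)):
                fh.write(
                    f"snp{j + 1:04d}\t{self.maf[j]!r}\t"
                    f"{self.snp_effects_exposure[j]!r}\t"
                    f"{self.snp_effects_outcome[j]!r}\n"
                )


def liability_to_binary(liability, prevalence: float) -> np.ndarray:
    """Dichotomize a latent liability at its empirical upper quantile.

    Returns the indicator of liability strictly exceeding the empirical
    ``1 - prevalence`` quantile, so the realized case fraction matches the
    target prevalence exactly up to ties.
    """
    liability = np.asarray(liability, dtype=float)
    if liability.size == 0:
        raise ValueError("empty liability vector")
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0, 1)")
    cut = np.quantile(liability, 1.0 - prevalence)
    return (liability > cut).astype(np.int64)


def simulate_cohort(config: SimConfig) -> Tuple[GenotypeMatrix, pd.DataFrame, TrueParams]:
    """Draw one cohort: genotypes, phenotype table and ground truth.

    Draw order (fixed; all from one PCG64 stream): allele frequencies,
    allele labels, per-SNP exposure effects, per-SNP pleiotropic outcome
    effects, covariate nuisance effects, genotypes, confounder, covariates,
    exposure noise, outcome noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_snps
    spec = config.covariate_spec

    # --- variant panel ---------------------------------------------------
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    allele_idx = np.array([rng.choice(4, size=2, replace=False) for _ in range(m)])
    counted = _NUCLEOTIDES[allele_idx[:, 0]]
    other = _NUCLEOTIDES[allele_idx[:, 1]]
    snp_ids = np.array([f"snp{j + 1:04d}" for j in range(m)])

    gamma = rng.normal(0.0, config.snp_effect_scale, size=m)
    if config.pleiotropy_mode == "none":
        pi = np.zeros(m)
    elif config.pleiotropy_mode == "balanced":
        pi = rng.normal(0.0, config.pleiotropy_scale, size=m)
    else:  # directional: constant added to every SNP's outcome effect
        pi = np.full(m, config.pleiotropy_scale)

    # small nonzero nuisance effects so adjustment matters downstream
    cov_fx = {
        "age": float(rng.normal(0.0, 0.005)),
        "sex": float(rng.normal(0.0, 0.05)),
        "centre": rng.normal(0.0, 0.05, size=spec.n_centres),
        "pc": rng.normal(0.0, 0.02, size=spec.n_pcs),
    }
    cov_fy = {
        "age": float(rng.normal(0.0, 0.005)),
        "sex": float(rng.normal(0.0, 0.05)),
        "centre": rng.normal(0.0, 0.05, size=spec.n_centres),
        "pc": rng.normal(0.0, 0.02, size=spec.n_pcs),
    }

    # --- individuals -----------------------------------------------------
    dosages = rng.binomial(2, maf[None, :], size=(n, m)).astype(float)
    confounder = rng.standard_normal(n)
    age = rng.uniform(spec.age_range[0], spec.age_range[1], size=n)
    sex = (rng.random(n) < spec.male_fraction).astype(np.int64)  # 1 = male
    centre = rng.integers(0, spec.n_centres, size=n)
    pcs = rng.standard_normal((n, spec.n_pcs))
    eps_x = rng.normal(0.0, config.noise_sd_x, size=n)
    eps_y = rng.normal(0.0, config.noise_sd_y, size=n)

    age_c = age - age.mean()
    cov_part_x = (cov_fx["age"] * age_c + cov_fx["sex"] * sex
                  + cov_fx["centre"][centre] + pcs @ cov_fx["pc"])
    cov_part_y = (cov_fy["age"] * age_c + cov_fy["sex"] * sex
                  + cov_fy["centre"][centre] + pcs @ cov_fy["pc"])

    liability_x = dosages @ gamma + config.confounder_effect_x * confounder \
        + cov_part_x + eps_x
    if config.exposure_kind == "binary":
        exposure = liability_to_binary(liability_x, config.prevalence).astype(float)
    else:
        exposure = liability_x

    liability_y = config.causal_effect * exposure \
        + config.confounder_effect_y * confounder \
        + dosages @ pi + cov_part_y + eps_y
    if config.outcome_kind == "binary":
        outcome = liability_to_binary(liability_y, config.outcome_prevalence).astype(float)
    else:
        outcome = liability_y

    iids = np.array([f"id{i + 1:06d}" for i in range(n)])
    variants = pd.DataFrame(
        {"snp": snp_ids, "counted_allele": counted, "other_allele": other,
         "maf": maf}
    )
    genotypes = GenotypeMatrix(iids=iids, variants=variants, dosages=dosages)

    cohort = pd.DataFrame({"iid": iids, "age": age, "sex": sex, "centre": centre})
    for k in range(spec.n_pcs):
        cohort[f"pc{k + 1}"] = pcs[:, k]
    cohort["exposure"] = exposure
    cohort["outcome"] = outcome

    truth = TrueParams(
        maf=maf,
        snp_effects_exposure=gamma,
        snp_effects_outcome=pi,
        causal_effect=config.causal_effect,
        confounder_effect_x=config.confounder_effect_x,
        confounder_effect_y=config.confounder_effect_y,
        covariate_effects_x=cov_fx,
        covariate_effects_y=cov_fy,
    )
    return genotypes, cohort, truth


def covariate_columns(cohort: pd.DataFrame) -> list:
    """Names of the nuisance covariate columns in a simulated cohort table."""
    return [c for c in cohort.columns
            if c in ("age", "sex", "centre") or c.startswith("pc")]


def simulate_summary_stats(
    seed: int,
    n_snps: int = 30,
    causal_effect: float = 0.0,
    beta_exp_range: Tuple[float, float] = (0.05, 0.15),
    se_exp: float = 0.01,
    se_out: float = 0.05,
    pleiotropy_mode: str = "none",
    pleiotropy_scale: float = 0.0,
    n: int = 10_000,
) -> pd.DataFrame:
    """Draw per-variant GWAS summary statistics directly.

    A lightweight two-level generator for calibrating the summary-statistic
    estimators: true per-SNP exposure associations are uniform on
    ``beta_exp_range``; observed associations add Gaussian estimation noise
    at the stated standard errors; the outcome association of SNP j is
    ``causal_effect * beta_exp_j`` plus the pleiotropy term (same modes as
    :class:`SimConfig`).
    """
    rng = np.random.default_rng(seed)
    bx_true = rng.uniform(*beta_exp_range, size=n_snps)
    if pleiotropy_mode == "none":
        pi = np.zeros(n_snps)
    elif pleiotropy_mode == "balanced":
        pi = rng.normal(0.0, pleiotropy_scale, size=n_snps)
    elif pleiotropy_mode == "directional":
        pi = np.full(n_snps, pleiotropy_scale)
    else:
        raise ValueError(f"unknown pleiotropy_mode {pleiotropy_mode!r}")
    by_true = causal_effect * bx_true + pi
    bx = bx_true + rng.normal(0.0, se_exp, size=n_snps)
    by = by_true + rng.normal(0.0, se_out, size=n_snps)
    pz = 2.0 * _norm_sf(np.abs(bx) / se_exp)
    return pd.DataFrame({
        "snp": [f"snp{j + 1:04d}" for j in range(n_snps)],
        "beta_exp": bx, "se_exp": se_exp, "pval_exp": pz,
        "beta_out": by, "se_out": se_out, "n": n,
    })


def _norm_sf(z):
    from scipy.stats import norm
    return norm.sf(z)


def write_cohort(outdir, genotypes: GenotypeMatrix, cohort: pd.DataFrame,
                 truth: TrueParams) -> None:
    """Write a simulated cohort as plain tab-separated text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genotypes.to_tsv(outdir / "dosages.tsv", outdir / "variants.tsv")
    cohort.to_csv(outdir / "cohort.tsv", sep="\t", index=False)
    truth.write(outdir / "true_params.tsv")


def config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a plain dict (e.g. parsed YAML)."""
    d = dict(d)
    if "covariate_spec" in d and isinstance(d["covariate_spec"], dict):
        cs = dict(d["covariate_spec"])
        if "age_range" in cs:
            cs["age_range"] = tuple(cs["age_range"])
        d["covariate_spec"] = CovariateSpec(**cs)
    if "maf_range" in d:
        d["maf_range"] = tuple(d["maf_range"])
    valid = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - valid
    if unknown:
        raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
    return SimConfig(**d)
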