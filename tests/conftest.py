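import numpy as np
import pandas as pd
import pytest

from mrsoc import SimConfig, simulate_cohort, covariate_design, covariate_columns


def oracle_weights(genotypes, truth, se=0.01, pval=1e-10):
    """Weights table carrying the true per-allele exposure effects.

    Emulates an external GWAS whose estimates are precise; the effect
    allele is the panel's counted allele, so no harmonization flips apply.
    """
    v = genotypes.variants
    return pd.DataFrame({
        "snp": v["snp"].to_numpy(),
        "effect_allele": v["counted_allele"].to_numpy(),
        "other_allele": v["other_allele"].to_numpy(),
        "beta": np.asarray(truth.snp_effects_exposure, dtype=float),
        "se": se,
        "pval": pval,
    })


@pytest.fixture(scope="session")
def small_cohort():
    """One modest confounded cohort shared by read-only tests."""
    cfg = SimConfig(seed=7, n_individuals=4000, n_snps=20)
    genotypes, cohort, truth = simulate_cohort(cfg)
    cov = covariate_design(cohort, covariate_columns(cohort))
    return cfg, genotypes, cohort, truth, cov
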