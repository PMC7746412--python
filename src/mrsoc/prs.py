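"""Weighted allele scores: reading GWAS weights, allele harmonization and
polygenic risk score (PRS) construction.

A PRS is the per-individual sum of effect-allele dosages weighted by the
GWAS per-allele regression coefficients; it serves as the instrumental
variable downstream. Before scoring, weights must be harmonized to the
genotype panel: where the panel counts the GWAS effect allele the weight is
kept, where it counts the other allele the weight is negated, and variants
absent from the panel or with irreconcilable alleles are dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WEIGHTS_COLUMNS = ["snp", "effect_allele", "other_allele", "beta", "se", "pval"]
_MANDATORY = ["snp", "effect_allele", "other_allele", "beta"]

#: strand-ambiguous (palindromic) allele pairs
AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class GenotypeMatrix:
    """Individuals × variants dosage matrix with variant panel metadata.

    ``variants`` carries at least ``snp``, ``counted_allele`` and
    ``other_allele``; ``dosages`` holds per-individual counted-allele
    dosages in [0, 2] with NaN for missing calls.
    """

    iids: np.ndarray
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.iids = np.asarray(self.iids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.iids), len(self.variants)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} inconsistent with "
                f"{len(self.iids)} individuals x {len(self.variants)} variants"
            )
        ids = self.variants["snp"]
        if ids.duplicated().any():
            raise ValueError("duplicate variant ids in panel")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.any(bad):
            raise ValueError("dosages outside [0, 2]")

    @property
    def n_individuals(self) -> int:
        return len(self.iids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_individuals(self, iids) -> "GenotypeMatrix":
        """Row subset in the order of ``iids``."""
        pos = pd.Series(np.arange(self.n_individuals), index=self.iids)
        idx = pos.loc[np.asarray(iids)].to_numpy()
        return GenotypeMatrix(
            iids=self.iids[idx],
            variants=self.variants.reset_index(drop=True),
            dosages=self.dosages[idx],
        )

    def flip_variant(self, snp_id: str) -> "GenotypeMatrix":
        """Relabel one variant's alleles and complement its dosages (d → 2−d).

        The same genetic information stored with the opposite counted
        allele; scores and IV estimates must be invariant to this.
        """
        variants = self.variants.copy()
        j = variants.index[variants["snp"] == snp_id]
        if len(j) != 1:
            raise KeyError(f"variant {snp_id!r} not in panel")
        j = j[0]
        a, b = variants.loc[j, "counted_allele"], variants.loc[j, "other_allele"]
        variants.loc[j, "counted_allele"], variants.loc[j, "other_allele"] = b, a
        dos = self.dosages.copy()
        dos[:, j] = 2.0 - dos[:, j]
        return GenotypeMatrix(iids=self.iids.copy(), variants=variants, dosages=dos)

    def to_tsv(self, dosage_path, variants_path=None) -> None:
        df = pd.DataFrame(self.dosages, columns=self.variants["snp"].to_numpy())
        df.insert(0, "iid", self.iids)
        df.to_csv(dosage_path, sep="\t", index=False)
        if variants_path is not None:
            self.variants.to_csv(variants_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, dosage_path, variants_path) -> "GenotypeMatrix":
        df = pd.read_csv(dosage_path, sep="\t")
        variants = pd.read_csv(variants_path, sep="\t")
        iids = df["iid"].to_numpy()
        dosages = df.drop(columns="iid")
        if list(dosages.columns) != list(variants["snp"]):
            raise ValueError("dosage columns do not match variant panel order")
        return cls(iids=iids, variants=variants, dosages=dosages.to_numpy(float))


@dataclass
class PRSVector:
    """Per-individual weighted allele score (the instrument)."""

    iids: np.ndarray
    score: np.ndarray
    n_variants_used: int
    n_missing: np.ndarray  # per-individual count of missing dosages scored as 0

    def to_series(self) -> pd.Series:
        return pd.Series(self.score, index=self.iids, name="prs")

    def to_tsv(self, path) -> None:
        pd.DataFrame({"iid": self.iids, "score": self.score}).to_csv(
            path, sep="\t", index=False
        )


def validate_weights(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"weights table missing mandatory columns: {missing}")
    dup = df.loc[df["snp"].duplicated(), "snp"]
    if len(dup):
        raise ValueError(f"duplicate variant ids in weights: {sorted(set(dup))}")
    same = df["effect_allele"] == df["other_allele"]
    if same.any():
        raise ValueError(
            f"effect and other allele identical for {df.loc[same, 'snp'].tolist()}"
        )
    if "se" in df.columns:
        bad_se = df["se"].notna() & (df["se"] <= 0)
        if bad_se.any():
            raise ValueError("non-positive standard errors in weights")
    return df


def read_weights(path_or_buf) -> pd.DataFrame:
    """Read a tab-separated GWAS weights table.

    Header must provide at least ``snp effect_allele other_allele beta``;
    rows with missing beta are dropped with a warning. Strand-ambiguous
    (A/T, C/G) variants are kept but listed in a warning since they cannot
    be checked against strand flips in real data.
    """
    df = pd.read_csv(path_or_buf, sep="\t", dtype={"snp": str})
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"weights table missing mandatory columns: {missing}")
    df["beta"] = pd.to_numeric(df["beta"], errors="raise")
    n_dropped = int(df["beta"].isna().sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} weight rows with missing beta")
        logger.info("read_weights: dropped %d rows with missing beta", n_dropped)
        df = df[df["beta"].notna()]
    df = df.reset_index(drop=True)
    validate_weights(df)
    ambig = [
        row.snp for row in df.itertuples()
        if frozenset((str(row.effect_allele), str(row.other_allele))) in AMBIGUOUS_PAIRS
    ]
    if ambig:
        warnings.warn(
            f"{len(ambig)} strand-ambiguous variants kept: {ambig[:10]}"
        )
    return df


def write_weights(df: pd.DataFrame, path) -> None:
    cols = [c for c in WEIGHTS_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


def harmonize(weights: pd.DataFrame, panel: GenotypeMatrix) -> pd.DataFrame:
    """Align weights to the panel's counted alleles, in panel order.

    Effect allele equal to the counted allele keeps its beta; equal to the
    panel's other allele gets its beta negated (the score then counts the
    opposite allele). Variants absent from the panel or with mismatched
    allele pairs are dropped and logged.
    """
    validate_weights(weights)
    if len(weights) == 0 or panel.n_variants == 0:
        raise ValueError("empty weights table or genotype panel")
    w = weights.set_index("snp")
    rows = []
    n_absent = n_mismatch = 0
    for rec in panel.variants.itertuples():
        if rec.snp not in w.index:
            n_absent += 1
            continue
        rw = w.loc[rec.snp]
        ea, oa = str(rw["effect_allele"]), str(rw["other_allele"])
        if ea == rec.counted_allele and oa == rec.other_allele:
            beta = float(rw["beta"])
        elif ea == rec.other_allele and oa == rec.counted_allele:
            beta = -float(rw["beta"])
        else:
            n_mismatch += 1
            continue
        rows.append({
            "snp": rec.snp,
            "effect_allele": rec.counted_allele,
            "other_allele": rec.other_allele,
            "beta": beta,
            "se": float(rw["se"]) if "se" in rw.index and pd.notna(rw.get("se")) else np.nan,
            "pval": float(rw["pval"]) if "pval" in rw.index and pd.notna(rw.get("pval")) else np.nan,
        })
    if n_absent or n_mismatch:
        logger.info(
            "harmonize: %d variants absent from panel, %d allele mismatches dropped",
            n_absent, n_mismatch,
        )
    if not rows:
        raise ValueError("no overlapping variants between weights and panel")
    return pd.DataFrame(rows, columns=WEIGHTS_COLUMNS)


def compute_prs(genotypes: GenotypeMatrix, weights: pd.DataFrame) -> PRSVector:
    """Score = Σ_j beta_j × dosage_ij over the weighted variants.

    Weights must already be harmonized to the panel (effect allele equal to
    the counted allele). Missing dosages contribute 0 to the score and are
    counted per individual for downstream filtering; no mean imputation is
    performed.
    """
    validate_weights(weights)
    panel_pos = pd.Series(
        np.arange(genotypes.n_variants), index=genotypes.variants["snp"]
    )
    used = weights[weights["snp"].isin(panel_pos.index)]
    if len(used) == 0:
        raise ValueError("no overlapping variants between weights and panel")
    mismatched = used["effect_allele"].to_numpy() != (
        genotypes.variants.set_index("snp")
        .loc[used["snp"], "counted_allele"]
        .to_numpy()
    )
    if mismatched.any():
        raise ValueError(
            "weights not harmonized to panel (effect allele != counted allele); "
            "run harmonize() first"
        )
    idx = panel_pos.loc[used["snp"]].to_numpy()
    dos = genotypes.dosages[:, idx]
    betas = used["beta"].to_numpy(float)
    missing = np.isnan(dos)
    score = np.where(missing, 0.0, dos) @ betas
    return PRSVector(
        iids=genotypes.iids.copy(),
        score=score,
        n_variants_used=len(used),
        n_missing=missing.sum(axis=1).astype(np.int64),
    )


@dataclass
class CorrelationResult:
    r: float
    r2: float
    n: int


def prs_correlation(a: PRSVector, b: PRSVector) -> CorrelationResult:
    """Pearson correlation (and r²) between two scores on shared individuals.

    Pairwise-complete: individuals with a missing score on either side are
    dropped. Used to check that different exposures' instruments carry
    essentially independent genetic information (r² ≈ 0).
    """
    sa, sb = a.to_series(), b.to_series()
    joined = pd.concat([sa, sb], axis=1, join="inner", keys=["a", "b"]).dropna()
    if len(joined) < 3:
        raise ValueError("fewer than 3 complete pairs")
    x, y = joined["a"].to_numpy(), joined["b"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a score; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    return CorrelationResult(r=r, r2=r * r, n=len(joined))
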