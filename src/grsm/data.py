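"""Core in-memory containers for the genotype/phenotype analysis.

Genotypes are stored as minor-allele dosages (0, 1, 2) in an int8 matrix with
-1 marking missing calls; SNP metadata travels in a pandas DataFrame indexed
by SNP id.  Sample-level covariates, exposures and traits live in an ordinary
DataFrame (one row per sample) — see :mod:`grsm.simulate` for the column
conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: covariates adjusted in every regression model (besides ancestry PCs)
DEFAULT_COVARIATES = ("sex", "age", "education", "drinking", "smoking")

#: the five obesity measures analysed
TRAITS = ("BMI", "BFP", "WC", "HC", "WHR")


@dataclass
class GenotypeMatrix:
    """Samples × SNPs dosage matrix with SNP metadata.

    Parameters
    ----------
    genotypes:
        ``(n_samples, n_snps)`` int8 array of minor-allele (A1) counts;
        ``-1`` encodes a missing call.
    snps:
        DataFrame indexed by SNP id with columns ``chrom`` (int),
        ``pos`` (1-based bp), ``a1`` (minor allele) and ``a2``.
    sample_ids:
        sequence of sample identifiers, one per row.
    """

    genotypes: np.ndarray
    snps: pd.DataFrame
    sample_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (samples x snps)")
        n, m = self.genotypes.shape
        if len(self.snps) != m:
            raise ValueError(
                f"snp table has {len(self.snps)} rows but matrix has {m} SNPs"
            )
        if self.sample_ids is None:
            self.sample_ids = np.array([f"S{i:06d}" for i in range(n)])
        else:
            self.sample_ids = np.asarray(self.sample_ids)
            if len(self.sample_ids) != n:
                raise ValueError("sample_ids length mismatch")

    # -- basic shape ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> pd.Index:
        return self.snps.index

    # -- per-SNP summaries ------------------------------------------------
    def genotype_counts(self):
        """Counts of hom-major (dosage 0), het (1) and hom-minor (2) calls.

        Returns three int arrays ``(n_aa, n_Aa, n_AA)`` of length n_snps,
        where A denotes the minor (A1) allele.
        """
        g = self.genotypes
        n_aa = (g == 0).sum(axis=0)
        n_Aa = (g == 1).sum(axis=0)
        n_AA = (g == 2).sum(axis=0)
        return n_aa, n_Aa, n_AA

    def call_rate(self) -> np.ndarray:
        return (self.genotypes != MISSING).mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Sample frequency of the A1 (minor) allele, missing calls excluded."""
        g = self.genotypes
        obs = g != MISSING
        n_obs = obs.sum(axis=0)
        tot = np.where(obs, g, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n_obs > 0, tot / (2.0 * n_obs), np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    # -- dosage views -----------------------------------------------------
    def dosages(self, impute: bool = True) -> np.ndarray:
        """Float dosage matrix; missing calls become the per-SNP mean (or NaN)."""
        g = self.genotypes.astype(np.float64)
        miss = self.genotypes == MISSING
        g[miss] = np.nan
        if impute and miss.any():
            col_mean = np.nanmean(g, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.where(miss)
            g[idx] = col_mean[idx[1]]
        return g

    # -- subsetting -------------------------------------------------------
    def subset_snps(self, ids) -> "GenotypeMatrix":
        """Return a new matrix restricted to ``ids`` (order preserved as given)."""
        loc = self.snps.index.get_indexer(pd.Index(ids))
        if (loc < 0).any():
            missing = pd.Index(ids)[loc < 0]
            raise KeyError(f"unknown SNP ids: {list(missing[:5])}...")
        return GenotypeMatrix(
            self.genotypes[:, loc], self.snps.iloc[loc].copy(), self.sample_ids
        )

    def subset_samples(self, ids) -> "GenotypeMatrix":
        index = pd.Index(self.sample_ids)
        loc = index.get_indexer(pd.Index(ids))
        if (loc < 0).any():
            raise KeyError("unknown sample ids in subset_samples")
        return GenotypeMatrix(
            self.genotypes[loc, :], self.snps.copy(), np.asarray(ids)
        )


def zscore(x: np.ndarray) -> np.ndarray:
    """Center to mean 0 and scale to (population) s.d. 1."""
    x = np.asarray(x, dtype=np.float64)
    sd = x.std()
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot z-score a zero-variance vector")
    return (x - x.mean()) / sd
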