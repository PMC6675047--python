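"""Ancestry principal components for population-stratification adjustment.

Computed from the post-QC, LD-pruned genotype matrix: per-SNP mean
imputation, centering, and scaling either by the sample standard deviation
(default, robust to MAF misestimation) or by the binomial s.d.
sqrt(2p(1-p)).  Coordinates are the top-k left singular vectors; each
component's largest-magnitude SNP loading is made positive so signs are
reproducible across solvers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .data import GenotypeMatrix

__all__ = ["AncestryPCs", "compute_pcs"]


@dataclass
class AncestryPCs:
    coords: pd.DataFrame          # samples × k, columns PC1..PCk
    explained_var: np.ndarray     # shares, non-increasing
    loadings: pd.DataFrame        # SNPs × k


def compute_pcs(G: GenotypeMatrix, k: int = 10, scale: str = "sample_sd",
                random_state: int = 0) -> AncestryPCs:
    """Top-k ancestry PCs of the standardized dosage matrix."""
    if k >= min(G.n_samples, G.n_snps):
        raise ValueError(
            f"k={k} must be < min(n_samples, n_snps)="
            f"{min(G.n_samples, G.n_snps)}")
    X = G.dosages(impute=True)
    X = X - X.mean(axis=0)
    if scale == "sample_sd":
        sd = X.std(axis=0)
    elif scale == "binomial":
        p = G.allele_freq()
        sd = np.sqrt(2.0 * p * (1.0 - p))
    else:
        raise ValueError("scale must be 'sample_sd' or 'binomial'")
    nz = sd > 0
    X[:, nz] /= sd[nz]
    X[:, ~nz] = 0.0

    solver = "randomized" if min(X.shape) > 500 else "full"
    pca = PCA(n_components=k, svd_solver=solver, random_state=random_state)
    coords = pca.fit_transform(X)
    load = pca.components_.T              # SNPs × k

    # sign convention: largest-|loading| entry positive per component
    for j in range(k):
        i = np.argmax(np.abs(load[:, j]))
        if load[i, j] < 0:
            load[:, j] *= -1
            coords[:, j] *= -1

    cols = [f"PC{j + 1}" for j in range(k)]
    return AncestryPCs(
        coords=pd.DataFrame(coords, index=pd.Index(G.sample_ids,
                                                   name="sample_id"),
                            columns=cols),
        explained_var=pca.explained_variance_ratio_.copy(),
        loadings=pd.DataFrame(load, index=G.snp_ids, columns=cols),
    )
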