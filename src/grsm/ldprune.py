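"""Sliding-window variance-inflation-factor LD pruning.

Mirrors the semantics of the classic ``--indep <window> <step> <vif>``
invocation: within each window of consecutive SNPs on a chromosome, the SNP
whose dosage is best predicted by the others (VIF = 1/(1 - R²) above the
cutoff) is removed, highest VIF first, until the window is clean; the window
then advances by ``step`` SNPs.  Passes repeat until stable, so the final
kept set satisfies the window criterion under a verification re-scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypeMatrix

__all__ = ["PruneParams", "window_vif", "vif_prune"]


@dataclass
class PruneParams:
    window_size: int = 50
    step: int = 5
    vif_max: float = 2.0

    def validate(self) -> None:
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if not (1 <= self.step <= self.window_size):
            raise ValueError("step must satisfy 1 <= step <= window_size")
        if self.vif_max <= 1:
            raise ValueError("vif_max must be > 1")


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute NaNs, center, unit-scale columns; zero-variance -> 0."""
    X = np.array(X, dtype=np.float64)
    if np.isnan(X).any():
        mu = np.nanmean(X, axis=0)
        mu = np.where(np.isnan(mu), 0.0, mu)
        idx = np.where(np.isnan(X))
        X[idx] = mu[idx[1]]
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    nz = sd > 0
    X[:, nz] /= sd[nz]
    X[:, ~nz] = 0.0
    return X, nz


def _vif_from_corr(R: np.ndarray, nz: np.ndarray) -> np.ndarray:
    """Per-SNP VIF from a window correlation matrix.

    Zero-variance SNPs get VIF 1 (they cannot inflate); exact collinearity
    yields +inf.
    """
    m = R.shape[0]
    vif = np.ones(m)
    act = np.where(nz)[0]
    if act.size < 2:
        return vif
    Ra = R[np.ix_(act, act)]
    try:
        inv = np.linalg.inv(Ra)
        d = np.diag(inv)
        if np.all(d >= 1.0 - 1e-8):
            d = np.maximum(d, 1.0)
            # R^2 within 1e-12 of 1 is exact collinearity
            vif[act] = np.where(d >= 1e12, np.inf, d)
            return vif
    except np.linalg.LinAlgError:
        pass
    # singular or numerically unreliable: per-SNP pseudo-inverse route
    for pos, i in enumerate(act):
        others = np.delete(act, pos)
        if others.size == 0:
            continue
        r = R[i, others]
        Ro = R[np.ix_(others, others)]
        r2 = float(r @ np.linalg.pinv(Ro) @ r)
        vif[i] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - min(max(r2, 0.0), 1.0 - 1e-15))
    return vif


def window_vif(G_window: np.ndarray) -> np.ndarray:
    """VIF of each SNP in a dosage window (samples × SNPs, NaN = missing).

    VIF_i = 1/(1 - R²_i) with R²_i from regressing the mean-imputed,
    centered dosage of SNP i on all other SNPs in the window.
    """
    X = np.asarray(G_window, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("window must be 2-D with at least 2 SNPs")
    Z, nz = _standardize(X)
    n = Z.shape[0]
    R = (Z.T @ Z) / n
    np.fill_diagonal(R, 1.0)
    return _vif_from_corr(R, nz)


def _clean_window(Z: np.ndarray, nz: np.ndarray, vif_max: float):
    """Indices (within the window) to drop so that all remaining VIF <= max.

    Greedy: repeatedly drop the highest-VIF SNP, ties broken toward the
    later position.
    """
    n = Z.shape[0]
    active = list(range(Z.shape[1]))
    dropped = []
    while len(active) >= 2:
        Za = Z[:, active]
        R = (Za.T @ Za) / n
        np.fill_diagonal(R, 1.0)
        vif = _vif_from_corr(R, nz[active])
        worst = vif.max()
        if worst <= vif_max:
            break
        # argmax with later-position tie-break
        cand = np.where(vif == worst)[0] if np.isfinite(worst) else \
            np.where(np.isinf(vif))[0]
        k = int(cand.max())
        dropped.append(active.pop(k))
    return dropped


def vif_prune(G: GenotypeMatrix, params: PruneParams | None = None) -> pd.Index:
    """Prune SNPs so no sliding window retains a VIF above the cutoff.

    SNPs must be ordered by (chromosome, position); chromosomes are pruned
    independently.  Returns the kept SNP ids, in input order.
    """
    params = params or PruneParams()
    params.validate()
    chrom = G.snps["chrom"].to_numpy()
    pos = G.snps["pos"].to_numpy()
    order_key = np.lexsort((pos, chrom))
    if not np.array_equal(order_key, np.arange(G.n_snps)):
        raise ValueError("SNPs must be sorted by (chromosome, position)")

    Z, nz = _standardize(G.dosages(impute=False))
    keep = np.ones(G.n_snps, dtype=bool)

    for c in np.unique(chrom):
        cidx = np.where(chrom == c)[0]
        while True:
            removed_this_pass = False
            kept = cidx[keep[cidx]]
            start = 0
            while start < len(kept):
                kept = cidx[keep[cidx]]
                if start >= len(kept):
                    break
                win = kept[start:start + params.window_size]
                if len(win) >= 2:
                    drop_local = _clean_window(Z[:, win], nz[win],
                                               params.vif_max)
                    if drop_local:
                        keep[win[drop_local]] = False
                        removed_this_pass = True
                start += params.step
            if not removed_this_pass:
                break

    return G.snp_ids[keep]
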