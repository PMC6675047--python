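"""Least-squares primitives shared by the scan and interaction modules.

A thin QR-based OLS (coefficients, classical standard errors, two-sided t
tests) plus Frisch–Waugh–Lovell residualization used to run hundreds of
thousands of per-SNP regressions as vectorized array operations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["OLSFit", "ols", "Residualizer"]


@dataclass
class OLSFit:
    names: list
    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    n: int
    df_resid: int
    estimable: bool

    def __getitem__(self, name: str):
        i = self.names.index(name)
        return dict(coef=self.coef[i], se=self.se[i], t=self.t[i],
                    p=self.p[i])


def ols(y: np.ndarray, X: np.ndarray, names=None) -> OLSFit:
    """Ordinary least squares with classical (unadjusted) standard errors.

    A rank-deficient design (within numerical tolerance) is returned with
    ``estimable=False`` and NaN statistics rather than raising: callers log
    and exclude such fits.
    """
    y = np.asarray(y, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    nan = np.full(p, np.nan)
    if n <= p:
        return OLSFit(list(names), nan, nan, nan, nan, n, 0, False)

    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    if diag.min() <= max(n, p) * np.finfo(float).eps * max(diag.max(), 1.0):
        return OLSFit(list(names), nan, nan, nan, nan, n, n - p, False)

    coef = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ coef
    df = n - p
    sigma2 = float(resid @ resid) / df
    Rinv = np.linalg.solve(R, np.eye(p))
    se = np.sqrt(np.maximum(np.sum(Rinv * Rinv, axis=1) * sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    return OLSFit(list(names), coef, se, t, pvals, n, df, True)


class Residualizer:
    """Project vectors/matrices off the column space of a base design."""

    def __init__(self, X0: np.ndarray):
        X0 = np.asarray(X0, dtype=np.float64)
        Q, R = np.linalg.qr(X0)
        diag = np.abs(np.diag(R))
        keep = diag > max(X0.shape) * np.finfo(float).eps * max(diag.max(), 1.0)
        # drop numerically collinear base columns (affects df bookkeeping)
        if not keep.all():
            Q = np.linalg.qr(X0[:, np.where(keep)[0]])[0]
        self.Q = Q
        self.rank = Q.shape[1]

    def __call__(self, A: np.ndarray) -> np.ndarray:
        A = np.asarray(A, dtype=np.float64)
        return A - self.Q @ (self.Q.T @ A)
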