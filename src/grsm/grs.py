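"""Internal-weight genetic risk scores under marginal-association filtering.

Per-SNP marginal scans (trait ~ dosage + covariates + ancestry PCs) provide
both the filter P-values and the score weights.  For each threshold t in a
10-value grid, the score sums β̂_SNP,j · dosage_j over SNPs with scan P < t
and is z-scored over the analysis sample.  An external-weight score (the
EuGRS analogue) aligns published per-allele weights to the genotyped minor
allele and is z-scored the same way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import DEFAULT_COVARIATES, GenotypeMatrix, zscore
from .linmod import Residualizer

__all__ = ["DEFAULT_THRESHOLDS", "marginal_scan", "GRSSet", "build_grs_set",
           "build_external_grs", "covariate_design"]

log = logging.getLogger(__name__)

#: the 10 marginal-association P-value filters
DEFAULT_THRESHOLDS = (0.0001, 0.00025, 0.0005, 0.001, 0.0025,
                      0.005, 0.01, 0.025, 0.05, 0.1)


def covariate_design(samples: pd.DataFrame, covariates=DEFAULT_COVARIATES,
                     pcs: pd.DataFrame | None = None):
    """Intercept + covariates (+ ancestry PCs), with column names."""
    cols = [np.ones(len(samples))]
    names = ["const"]
    for c in covariates:
        cols.append(samples[c].to_numpy(dtype=float))
        names.append(c)
    if pcs is not None:
        P = pcs.loc[samples.index]
        for c in P.columns:
            cols.append(P[c].to_numpy(dtype=float))
            names.append(c)
    return np.column_stack(cols), names


def marginal_scan(G: GenotypeMatrix, samples: pd.DataFrame, trait: str,
                  covariates=DEFAULT_COVARIATES,
                  pcs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-SNP OLS of the trait on dosage plus covariates.

    Rows of ``samples`` must align with ``G``; complete cases on the trait
    and covariates are used.  Returns a DataFrame indexed by SNP id with
    ``beta``, ``se``, ``t``, ``p`` and ``n``; SNPs whose (mean-imputed)
    dosage has zero variance are recorded with NaN statistics and logged.
    """
    used = [trait, *covariates]
    cc = samples[used].notna().all(axis=1).to_numpy()
    sub = samples.loc[cc]
    y = sub[trait].to_numpy(dtype=float)
    X0, _ = covariate_design(sub, covariates, pcs)

    D = G.dosages(impute=True)[cc, :]
    resid = Residualizer(X0)
    yt = resid(y)
    Dt = resid(D)

    num = Dt.T @ yt
    den = np.einsum("ij,ij->j", Dt, Dt)
    ok = den > 1e-12 * len(y)
    n_skip = int((~ok).sum())
    if n_skip:
        log.info("marginal_scan(%s): skipped %d zero-variance SNPs",
                 trait, n_skip)

    beta = np.full(G.n_snps, np.nan)
    se = np.full(G.n_snps, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta[ok] = num[ok] / den[ok]
    df = len(y) - resid.rank - 1
    yty = float(yt @ yt)
    rss = yty - beta * num
    sigma2 = rss / df
    se[ok] = np.sqrt(np.maximum(sigma2[ok], 0.0) / den[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tval), df)

    return pd.DataFrame({"beta": beta, "se": se, "t": tval, "p": pval,
                         "n": len(y)}, index=G.snp_ids)


@dataclass
class GRSSet:
    """Threshold-indexed SNP subsets and their weighted, z-scored scores."""

    trait: str
    thresholds: tuple
    members: dict                  # threshold -> pd.Index of SNP ids
    weights: dict                  # threshold -> pd.Series (scan beta)
    raw: pd.DataFrame              # samples × thresholds (NaN where absent)
    z: pd.DataFrame                # z-scored columns
    absent: list = field(default_factory=list)   # thresholds with no members

    def n_snps(self, threshold: float) -> int:
        return len(self.members.get(threshold, ()))


def build_grs_set(scan: pd.DataFrame, G: GenotypeMatrix,
                  thresholds=DEFAULT_THRESHOLDS,
                  trait: str = "") -> GRSSet:
    """Assemble the threshold grid of internal-weight scores.

    Member sets are nested across increasing thresholds by construction;
    each non-empty score column is z-scored over the sample.  Thresholds
    with no qualifying SNP (possible at 1e-4 on small cohorts) are flagged
    absent and excluded downstream while the Bonferroni multiplier stays 10.
    """
    thresholds = tuple(thresholds)
    if any(t2 <= t1 for t1, t2 in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    scan = scan.loc[G.snp_ids]
    D = G.dosages(impute=True)

    members, weights, absent = {}, {}, []
    raw = pd.DataFrame(index=pd.Index(G.sample_ids, name="sample_id"),
                       columns=[str(t) for t in thresholds], dtype=float)
    zsc = raw.copy()
    p = scan["p"].to_numpy()
    for t in thresholds:
        sel = np.where(np.isfinite(p) & (p < t))[0]
        ids = G.snp_ids[sel]
        members[t] = ids
        weights[t] = scan["beta"].iloc[sel]
        if sel.size == 0:
            absent.append(t)
            continue
        score = D[:, sel] @ scan["beta"].to_numpy()[sel]
        raw[str(t)] = score
        if score.std() == 0:
            absent.append(t)
            members[t] = ids
            continue
        zsc[str(t)] = zscore(score)
    if absent:
        log.info("build_grs_set(%s): %d empty/degenerate thresholds: %s",
                 trait, len(absent), absent)
    return GRSSet(trait=trait, thresholds=thresholds, members=members,
                  weights=weights, raw=raw, z=zsc, absent=absent)


def read_external_weights(path) -> pd.DataFrame:
    """Read a 3-column TSV of published weights: snp_id, effect_allele,
    weight."""
    w = pd.read_csv(path, sep="\t", dtype={"snp_id": str,
                                           "effect_allele": str})
    missing = {"snp_id", "effect_allele", "weight"} - set(w.columns)
    if missing:
        raise ValueError(f"external weights file lacks columns {missing}")
    return w


def build_external_grs(G: GenotypeMatrix, weights: pd.DataFrame):
    """Externally weighted score from a (snp_id, effect_allele, weight) table.

    Weights are aligned to the genotyped minor-allele dosage: when the
    recorded effect allele is the other (major) allele, the weight's sign is
    flipped (w * (2 - dosage) differs from -w * dosage by a constant, which
    z-scoring removes).  Returns ``(z_scores, report)`` where the report
    counts matched, allele-mismatched and unmatched weights.
    """
    w = weights.set_index("snp_id") if "snp_id" in weights.columns else weights
    matched = w.index.intersection(G.snp_ids)
    if len(matched) == 0:
        raise ValueError("no external weight matches a genotyped SNP id")

    sub = G.subset_snps(matched)
    eff = w.loc[matched, "effect_allele"].to_numpy()
    wt = w.loc[matched, "weight"].to_numpy(dtype=float)
    a1 = sub.snps["a1"].to_numpy()
    a2 = sub.snps["a2"].to_numpy()
    sign = np.where(eff == a1, 1.0, np.where(eff == a2, -1.0, np.nan))
    bad_allele = np.isnan(sign)
    use = ~bad_allele
    report = {"matched": int(use.sum()),
              "allele_mismatch": int(bad_allele.sum()),
              "unmatched": int(len(w) - len(matched))}
    if not use.any():
        raise ValueError("no external weight has an allele present in bim")

    score = sub.dosages(impute=True)[:, use] @ (wt[use] * sign[use])
    if score.std() == 0:
        raise ValueError("external score has zero variance; z-score undefined")
    return pd.Series(zscore(score), index=pd.Index(G.sample_ids,
                                                   name="sample_id")), report
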