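"""SNP- and sample-level quality control.

SNP QC is the sequential funnel call rate → Hardy–Weinberg exact test →
minor allele frequency, with per-stage removal counts.  Sample QC estimates
pairwise identity-by-descent sharing (PI-HAT = P(IBD=2) + 0.5·P(IBD=1)) by
the method of moments from observed identity-by-state counts, then greedily
removes one member of each related pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypeMatrix

__all__ = ["hwe_exact_test", "snp_stats", "snp_qc_filter", "QCResult",
           "pairwise_pihat", "prune_related"]


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------
def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy–Weinberg test P-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed table (two-sidedness by probability mass).

    Parameters are genotype counts; which homozygote is "AA" does not
    matter.  Returns a probability in (0, 1].
    """
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("total genotype count must be >= 1")

    rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if rare == 0:
        return 1.0

    # conditional distribution of the het count k over {rare%2, ..., rare}
    # step 2, via the standard ratio recurrence from the mode outward
    ks = np.arange(rare % 2, rare + 1, 2)
    mid = int(round(rare * (2 * n - rare) / (2.0 * n)))
    if mid % 2 != rare % 2:
        mid += 1
    mid = min(max(mid, ks[0]), rare)

    probs = np.zeros(ks.size)
    i_mid = (mid - ks[0]) // 2
    probs[i_mid] = 1.0
    # downward: P(k-2)/P(k) = k(k-1) / (4 (hom_r+1)(hom_c+1))
    for i in range(i_mid, 0, -1):
        k = ks[i]
        hom_r = (rare - k) // 2
        hom_c = n - k - hom_r
        probs[i - 1] = probs[i] * k * (k - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
    # upward: P(k+2)/P(k) = 4 hom_r hom_c / ((k+1)(k+2))
    for i in range(i_mid, ks.size - 1):
        k = ks[i]
        hom_r = (rare - k) // 2
        hom_c = n - k - hom_r
        probs[i + 1] = probs[i] * 4.0 * hom_r * hom_c / ((k + 1) * (k + 2))

    probs /= probs.sum()
    p_obs = probs[(n_Aa - ks[0]) // 2]
    p = probs[probs <= p_obs * (1.0 + 1e-10)].sum()
    if p >= 1.0 - 1e-12:     # observed table at the conditional mode
        return 1.0
    return float(p)


# ---------------------------------------------------------------------------
# SNP QC funnel
# ---------------------------------------------------------------------------
def snp_stats(G: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP call rate, genotype counts, MAF and HWE exact P."""
    n_aa, n_Aa, n_AA = G.genotype_counts()
    hwe_p = np.array([
        hwe_exact_test(aa, ab, bb) if (aa + ab + bb) > 0 else np.nan
        for aa, ab, bb in zip(n_AA, n_Aa, n_aa)
    ])
    return pd.DataFrame({
        "call_rate": G.call_rate(),
        "n_hom_major": n_aa, "n_het": n_Aa, "n_hom_minor": n_AA,
        "maf": G.maf(),
        "hwe_p": hwe_p,
    }, index=G.snp_ids)


@dataclass
class QCResult:
    kept_ids: pd.Index
    removed: dict          # stage -> count, in funnel order
    stats: pd.DataFrame

    @property
    def n_kept(self) -> int:
        return len(self.kept_ids)


def snp_qc_filter(G: GenotypeMatrix, call_rate_min: float = 0.95,
                  hwe_alpha: float = 5.7e-7,
                  maf_min: float = 0.01) -> QCResult:
    """Sequential SNP filter: call rate, then HWE, then MAF.

    Removal counts are reported per stage so the funnel arithmetic
    ``n_input - c1 - c2 - c3 = n_kept`` always holds; each stage only sees
    SNPs surviving the previous one.
    """
    for name, v in (("call_rate_min", call_rate_min),
                    ("hwe_alpha", hwe_alpha), ("maf_min", maf_min)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    if G.n_snps == 0:
        raise ValueError("empty genotype matrix")

    st = snp_stats(G)
    alive = np.ones(G.n_snps, dtype=bool)

    fail_cr = alive & (st["call_rate"].to_numpy() < call_rate_min)
    alive &= ~fail_cr
    fail_hwe = alive & (st["hwe_p"].to_numpy() < hwe_alpha)
    alive &= ~fail_hwe
    fail_maf = alive & (st["maf"].to_numpy() < maf_min)
    alive &= ~fail_maf

    removed = {"call_rate": int(fail_cr.sum()),
               "hwe": int(fail_hwe.sum()),
               "maf": int(fail_maf.sum())}
    return QCResult(kept_ids=G.snp_ids[alive], removed=removed, stats=st)


# ---------------------------------------------------------------------------
# method-of-moments IBD / PI-HAT
# ---------------------------------------------------------------------------
def pairwise_pihat(G: GenotypeMatrix, snp_subset=None,
                   min_pihat: float = 0.0) -> pd.DataFrame:
    """Method-of-moments IBD estimates for every sample pair.

    Observed IBS0/1/2 counts over SNPs non-missing in both samples are
    matched to their expectations given sample allele frequencies,
    yielding P(IBD=0), P(IBD=1), P(IBD=2).  PI-HAT is the clipped raw
    combination P2 + P1/2; the reported probabilities are then clipped and
    renormalized onto the simplex preserving that value, so every record
    satisfies ``pihat = p_ibd2 + 0.5 * p_ibd1`` exactly.  Returns one row
    per unordered pair (i < j); rows with pihat < ``min_pihat`` are
    dropped.
    """
    if G.n_samples < 2:
        raise ValueError("need at least 2 samples")
    Gs = G if snp_subset is None else G.subset_snps(snp_subset)

    p = Gs.allele_freq()
    informative = np.isfinite(p) & (p > 0) & (p < 1)
    if informative.sum() < 100:
        warnings.warn(
            f"only {int(informative.sum())} informative SNPs; "
            "IBD estimates will be unstable", stacklevel=2)
    g = Gs.genotypes[:, informative]
    p = p[informative]
    q = 1.0 - p

    # one-hot genotype indicators (float32 matmuls: counts stay exact)
    A0 = (g == 0).astype(np.float32)
    A1 = (g == 1).astype(np.float32)
    A2 = (g == 2).astype(np.float32)
    M = A0 + A1 + A2

    ibs0 = A0 @ A2.T
    ibs0 = ibs0 + ibs0.T
    ibs2 = A0 @ A0.T + A1 @ A1.T + A2 @ A2.T
    shared = M @ M.T
    ibs1 = shared - ibs0 - ibs2

    # per-SNP expected IBS-state probabilities given IBD state
    e00 = (2.0 * p**2 * q**2).astype(np.float32)
    e10 = (4.0 * p**3 * q + 4.0 * p * q**3).astype(np.float32)
    e11 = (2.0 * p**2 * q + 2.0 * p * q**2).astype(np.float32)

    S00 = (M * e00) @ M.T
    S10 = (M * e10) @ M.T
    S11 = (M * e11) @ M.T

    with np.errstate(divide="ignore", invalid="ignore"):
        P0 = np.where(S00 > 0, ibs0 / S00, 0.0).astype(np.float64)
        P1 = np.where(S11 > 0, (ibs1 - P0 * S10) / S11, 0.0).astype(np.float64)
    P2 = 1.0 - P0 - P1

    # PI-HAT from the raw moment estimates: the estimation errors of P1 and
    # P2 are strongly anticorrelated and cancel in P2 + P1/2, so clipping
    # the combination (rather than each component first) avoids inflating
    # kinship for unrelated pairs at modest SNP counts.
    pihat = np.clip(P2 + 0.5 * P1, 0.0, 1.0)

    # repair the reported probability triple onto the simplex while
    # preserving pihat = P2 + 0.5*P1 exactly
    z1 = np.clip(P1, 0.0, 1.0)
    z2 = np.clip(P2, 0.0, 1.0)
    k = z2 + 0.5 * z1
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(k > 0, pihat / np.where(k > 0, k, 1.0), 0.0)
    z1, z2 = z1 * scale, z2 * scale
    z2 = np.where((k <= 0) & (pihat > 0), pihat, z2)
    # if z1+z2 exceeds 1, shift mass from IBD1 to IBD2 at constant pihat
    over = z1 + z2 > 1.0
    z1 = np.where(over, 2.0 * (1.0 - pihat), z1)
    z2 = np.where(over, 2.0 * pihat - 1.0, z2)
    P1, P2 = z1, z2
    P0 = 1.0 - P1 - P2

    iu, ju = np.triu_indices(Gs.n_samples, k=1)
    out = pd.DataFrame({
        "sample_i": np.asarray(Gs.sample_ids)[iu],
        "sample_j": np.asarray(Gs.sample_ids)[ju],
        "p_ibd0": P0[iu, ju], "p_ibd1": P1[iu, ju], "p_ibd2": P2[iu, ju],
        "pihat": pihat[iu, ju],
        "n_shared": shared[iu, ju].astype(int),
    })
    if min_pihat > 0:
        out = out[out["pihat"] >= min_pihat].reset_index(drop=True)
    return out


def prune_related(records: pd.DataFrame, threshold: float = 0.125,
                  call_rates: pd.Series | None = None,
                  all_samples=None) -> list:
    """Greedy relatedness pruning: keep a set with no pair ≥ ``threshold``.

    While any kept pair violates the threshold, remove the sample involved
    in the most violating pairs; ties are broken by removing the lower call
    rate, then the higher sample index.  ``records`` must cover all
    candidate pairs (rows below threshold may be pre-filtered away).
    """
    if all_samples is None:
        all_samples = pd.unique(
            pd.concat([records["sample_i"], records["sample_j"]]))
    order = {s: k for k, s in enumerate(all_samples)}

    bad = records[records["pihat"] >= threshold]
    adj: dict = {}
    for i, j in zip(bad["sample_i"], bad["sample_j"]):
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)

    removed = set()
    while True:
        degrees = {s: len(nb - removed) for s, nb in adj.items()
                   if s not in removed}
        degrees = {s: d for s, d in degrees.items() if d > 0}
        if not degrees:
            break
        max_deg = max(degrees.values())
        cand = [s for s, d in degrees.items() if d == max_deg]
        if call_rates is not None and len(cand) > 1:
            lo = min(call_rates.get(s, 1.0) for s in cand)
            cand = [s for s in cand if call_rates.get(s, 1.0) == lo]
        victim = max(cand, key=lambda s: order.get(s, -1))
        removed.add(victim)

    return [s for s in all_samples if s not in removed]
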