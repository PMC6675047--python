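"""SNP-level QC funnel and relatedness exclusion.

SNPs pass call rate >= 95%, Hardy-Weinberg exact P >= 5.7e-7 and MAF >= 1%
in sequence; samples are screened by method-of-moments IBD sharing
(PI-HAT = P(IBD=2) + P(IBD=1)/2) and one member of each pair with
PI-HAT >= 0.125 (third-degree relatives or closer) is removed.
"""

from grsm import (SimConfig, pairwise_pihat, prune_related, simulate_genotypes,
                  snp_qc_filter)

cfg = SimConfig(n_samples=400, n_snps=4000, seed=11, frac_hwe_violating=0.02)
G, truth = simulate_genotypes(cfg)

qc = snp_qc_filter(G)   # defaults: 0.95 / 5.7e-7 / 0.01
print(f"SNP funnel: {G.n_snps} in -> removed "
      f"{qc.removed['call_rate']} (call rate), {qc.removed['hwe']} (HWE), "
      f"{qc.removed['maf']} (MAF) -> {qc.n_kept} kept")

ph = pairwise_pihat(G, qc.kept_ids)
top = ph.nlargest(5, "pihat")
print("\nhighest PI-HAT pairs (injected truth: duplicates ~1.0, "
      "parent-offspring ~0.5):")
print(top[["sample_i", "sample_j", "pihat"]].to_string(index=False))
print("truth:", truth.duplicate_pairs, "+", truth.po_pairs)

kept = prune_related(ph, threshold=0.125, all_samples=list(G.sample_ids))
print(f"\nrelatedness pruning kept {len(kept)} / {G.n_samples} samples "
      "(one member of each related pair removed)")
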