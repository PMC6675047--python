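"""End-to-end orchestration: synthesize (or read) → QC → prune → PCA →
scan → GRS → interaction inference → report.

Every stage writes its artifacts (TSV / PLINK / plain-text id lists) into
the run directory, records input/output counts in the log (the QC funnel),
and the run closes with a manifest listing every output file with a
checksum.  A fixed seed makes the whole run byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import TRAITS, DEFAULT_COVARIATES
from .grs import DEFAULT_THRESHOLDS, build_grs_set, marginal_scan
from .gxe import ALPHA_STUDY, run_analysis_matrix
from .ldprune import PruneParams, vif_prune
from .pca import compute_pcs
from .plinkio import read_plink, write_plink
from .qc import pairwise_pihat, prune_related, snp_qc_filter
from .simulate import SimConfig, simulate_cohort

__all__ = ["PipelineConfig", "run"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds default to the published analysis-plan constants."""

    # input: either a PLINK prefix + sample TSV, or a synthesis config
    plink_prefix: str | None = None
    sample_table: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)

    call_rate_min: float = 0.95
    hwe_alpha: float = 5.7e-7
    maf_min: float = 0.01
    pihat_max: float = 0.125
    pihat_on_pruned: bool = True      # estimate IBD on the LD-pruned set
    prune: PruneParams = field(default_factory=PruneParams)
    k_pcs: int = 10
    thresholds: tuple = DEFAULT_THRESHOLDS
    alpha_study: float = ALPHA_STUDY
    traits: tuple = TRAITS
    sex_stratified: bool = False     # additionally re-run per sex
    seed: int = 0

    def to_dict(self) -> dict:
        def plain(x):
            if isinstance(x, dict):
                return {k: plain(v) for k, v in x.items()}
            if isinstance(x, (tuple, list)):
                return [plain(v) for v in x]
            return x
        return plain(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimConfig(**{**d["sim"], "maf_range":
                                    tuple(d["sim"].get("maf_range", (0.01, 0.5))),
                                    "missing_rate_range":
                                    tuple(d["sim"].get("missing_rate_range",
                                                       (0.0, 0.02)))})
        if "prune" in d and isinstance(d["prune"], dict):
            d["prune"] = PruneParams(**d["prune"])
        for key in ("thresholds", "traits"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute the full pipeline; returns the run directory."""
    t_start = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    plog = logging.getLogger("grsm.pipeline.run")
    plog.setLevel(logging.INFO)
    plog.addHandler(handler)

    def stage(msg, *args):
        plog.info(msg, *args)
        log.debug(msg, *args)

    try:
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=False)

        # ---- stage 0: inputs -------------------------------------------
        if config.plink_prefix is not None:
            G = read_plink(config.plink_prefix)
            samples = pd.read_csv(config.sample_table, sep="\t",
                                  index_col="sample_id")
            samples = samples.loc[pd.Index(G.sample_ids)]
            truth = None
            stage("input: read %d samples x %d SNPs from %s",
                  G.n_samples, G.n_snps, config.plink_prefix)
        else:
            G, samples, truth = simulate_cohort(config.sim)
            samples = samples.set_axis(pd.Index(G.sample_ids,
                                                name="sample_id"))
            write_plink(G, outdir / "cohort",
                        sex=samples["sex"].to_numpy())
            _write_tsv(samples, outdir / "samples.tsv")
            pd.DataFrame({
                "pair_type": (["duplicate"] * len(truth.duplicate_pairs)
                              + ["parent_offspring"] * len(truth.po_pairs)),
                "i": [p[0] for p in truth.duplicate_pairs + truth.po_pairs],
                "j": [p[1] for p in truth.duplicate_pairs + truth.po_pairs],
            }).to_csv(outdir / "truth_relatives.tsv", sep="\t", index=False)
            causal = pd.concat(
                {t: df for t, df in truth.causal_snps.items()},
                names=["trait"]).reset_index()
            causal.to_csv(outdir / "truth_causal_snps.tsv", sep="\t",
                          index=False, float_format="%.10g")
            _write_tsv(pd.DataFrame(truth.burden,
                                    index=samples.index),
                       outdir / "truth_burden.tsv")
            stage("synthesized %d samples x %d SNPs (seed %d)",
                  G.n_samples, G.n_snps, config.sim.seed)

        # ---- stage 1: SNP QC -------------------------------------------
        qc = snp_qc_filter(G, config.call_rate_min, config.hwe_alpha,
                           config.maf_min)
        _write_tsv(qc.stats, outdir / "snp_qc.tsv")
        (outdir / "qc_kept_snps.txt").write_text(
            "\n".join(qc.kept_ids) + "\n")
        stage("snp_qc: %d in, removed call_rate=%d hwe=%d maf=%d, %d kept",
              G.n_snps, qc.removed["call_rate"], qc.removed["hwe"],
              qc.removed["maf"], qc.n_kept)
        G1 = G.subset_snps(qc.kept_ids)

        # ---- stage 2: LD pruning ---------------------------------------
        kept = vif_prune(G1, config.prune)
        pruned_out = G1.snp_ids.difference(kept)
        (outdir / "prune.in").write_text("\n".join(kept) + "\n")
        (outdir / "prune.out").write_text("\n".join(pruned_out) + "\n")
        stage("ld_prune: %d in, %d removed, %d kept",
              G1.n_snps, len(pruned_out), len(kept))
        G2 = G1.subset_snps(kept)

        # ---- stage 3: relatedness --------------------------------------
        G_ibd = G2 if config.pihat_on_pruned else G1
        pihat = pairwise_pihat(G_ibd)
        call_rates = pd.Series(
            (G_ibd.genotypes != -1).mean(axis=1),
            index=pd.Index(G_ibd.sample_ids))
        kept_samples = prune_related(
            pihat, config.pihat_max, call_rates,
            all_samples=list(G_ibd.sample_ids))
        _write_tsv(pihat[pihat["pihat"] >= 0.05], outdir / "pihat.tsv",
                   index=False)
        (outdir / "kept_samples.txt").write_text(
            "\n".join(kept_samples) + "\n")
        stage("relatedness: %d samples in, %d removed (PI-HAT >= %g), %d kept",
              G_ibd.n_samples, G_ibd.n_samples - len(kept_samples),
              config.pihat_max, len(kept_samples))
        G3 = G2.subset_samples(kept_samples)
        samples3 = samples.loc[kept_samples]

        # ---- stage 4: ancestry PCA -------------------------------------
        pcs = compute_pcs(G3, k=config.k_pcs, random_state=config.seed)
        _write_tsv(pcs.coords, outdir / "eigenvec.tsv")
        pd.Series(pcs.explained_var, name="explained_var_share").to_csv(
            outdir / "eigenval.tsv", sep="\t", index=False)
        stage("pca: %d components, leading share %.4f",
              config.k_pcs, pcs.explained_var[0])

        # ---- stage 5: scans + GRS --------------------------------------
        scans, grs_sets = {}, {}
        for trait in config.traits:
            scans[trait] = marginal_scan(G3, samples3, trait,
                                         DEFAULT_COVARIATES, pcs.coords)
            grs_sets[trait] = build_grs_set(scans[trait], G3,
                                            config.thresholds, trait=trait)
            _write_tsv(scans[trait], outdir / f"scan_{trait}.tsv")
            _write_tsv(grs_sets[trait].z, outdir / f"grs_{trait}.tsv")
            stage("scan %s: %d SNPs, grid sizes %s", trait, G3.n_snps,
                  [grs_sets[trait].n_snps(t) for t in config.thresholds])

        # ---- stage 6: analysis matrix ----------------------------------
        am = run_analysis_matrix(G3, samples3, pcs.coords,
                                 traits=config.traits,
                                 thresholds=config.thresholds,
                                 alpha_study=config.alpha_study,
                                 scans=scans, grs_sets=grs_sets)
        _write_tsv(am.interactions, outdir / "interactions.tsv", index=False)
        _write_tsv(am.mains, outdir / "main_effects.tsv", index=False)
        for facet in ("participation", "frequency", "duration"):
            _write_tsv(am.summary_table(facet),
                       outdir / f"table_{facet}.tsv")
        stage("analysis matrix: %d interaction + %d main-effect tests, "
              "alpha_study=%.3g, %d significant interactions",
              am.n_interaction_tests, am.n_main_effect_tests,
              config.alpha_study, int(am.interactions["significant"].sum()))

        # ---- stage 7: figure-style summaries ---------------------------
        # quartile means and per-exercise stratified GRS effects use the
        # 0.05-filter score (the conventional significance level)
        from .gxe import quartile_summary, stratified_grs_effect
        ref_t = 0.05 if 0.05 in config.thresholds else config.thresholds[-1]
        for trait in config.traits:
            gset = grs_sets[trait]
            if ref_t in gset.absent:
                continue
            z = gset.z[str(ref_t)]
            expo = samples3["regular_exercise"]
            ok = expo.notna() & samples3[trait].notna()
            q = quartile_summary(z[ok.to_numpy()], expo[ok],
                                 samples3.loc[ok, trait])
            _write_tsv(q, outdir / f"quartiles_{trait}.tsv")

            rows = []
            groups = [("no_exercise", samples3["regular_exercise"] == 0)]
            groups += [(s, samples3[f"ex_{s}"] == 1)
                       for s in [c[3:] for c in samples3.columns
                                 if c.startswith("ex_")]]
            for label, mask in groups:
                lab = pd.Series(np.where(mask, "in", "out"),
                                index=samples3.index)
                res = stratified_grs_effect(samples3, trait, z, lab,
                                            pcs=pcs.coords)
                if "in" in res.index:
                    r = res.loc["in"]
                    rows.append((label, r["beta_grs"], r["se"], r["p"],
                                 r["n"], r["flag"]))
                else:
                    rows.append((label, np.nan, np.nan, np.nan, 0,
                                 "empty_stratum"))
            pd.DataFrame(rows, columns=["stratum", "beta_grs", "se", "p",
                                        "n", "flag"]).to_csv(
                outdir / f"grs_by_exercise_{trait}.tsv", sep="\t",
                index=False, float_format="%.10g")
        stage("summaries: quartile and stratified-GRS tables written "
              "(filter %.3g)", ref_t)

        # ---- optional sex-stratified re-run ----------------------------
        if config.sex_stratified:
            covs = ("age", "education", "drinking", "smoking")
            for label, val in (("female", 1), ("male", 0)):
                sub = samples3[samples3["sex"] == val]
                Gs = G3.subset_samples(sub.index)
                am_s = run_analysis_matrix(
                    Gs, sub, pcs.coords.loc[sub.index],
                    traits=config.traits, thresholds=config.thresholds,
                    covariates=covs, alpha_study=config.alpha_study)
                _write_tsv(am_s.interactions,
                           outdir / f"interactions_{label}.tsv", index=False)
                _write_tsv(am_s.mains,
                           outdir / f"main_effects_{label}.tsv", index=False)
                stage("sex-stratified (%s): %d samples, %d interaction tests",
                      label, len(sub), am_s.n_interaction_tests)

        # ---- manifest ---------------------------------------------------
        handler.flush()
        files = sorted(p for p in outdir.iterdir()
                       if p.is_file() and p.name != "manifest.json")
        manifest = {
            "elapsed_seconds": round(time.time() - t_start, 2),
            "seed": config.seed,
            "alpha_study": config.alpha_study,
            "files": {p.name: _checksum(p) for p in files},
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2) + "\n")
        return outdir
    finally:
        plog.removeHandler(handler)
        handler.close()
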