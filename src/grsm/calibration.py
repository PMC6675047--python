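"""Monte-Carlo validation of the two-stage interaction procedure.

These routines exercise the whole internal-weight pipeline on synthetic
cohorts where the truth is known: type-I error of the single-threshold and
combined (×10, capped) interaction tests under the null, recovery of a
generative interaction effect, and the empirical independence between the
stage-1 marginal estimates and the stage-2 per-SNP interaction estimates
that justifies marginal-association filtering.

Genotypes here are drawn without LD, relatives, structure or missingness —
the regimes those features stress are covered by the QC modules — so each
replicate stays cheap enough for thousand-replicate calibrations.
"""

from __future__ import annotations

import numpy as np

from .data import DEFAULT_COVARIATES
from .grs import DEFAULT_THRESHOLDS, build_grs_set, marginal_scan
from .gxe import fit_interaction, fit_snp_interactions, grsm_pvalue
from .simulate import (SimConfig, TraitModel, simulate_covariates_exposures,
                       simulate_genotypes, simulate_phenotypes)

__all__ = ["null_replicate", "type1_error", "recovery_simulation",
           "two_stage_independence"]


def _fast_config(n: int, m: int, seed: int, **overrides) -> SimConfig:
    base = dict(n_samples=n, n_snps=m, within_block_corr=0.0,
                n_duplicate_pairs=0, n_po_pairs=0, n_subpops=1,
                subpop_divergence=0.0, missing_rate_range=(0.0, 0.0),
                frac_hwe_violating=0.0, n_exposure_nonresponse=0, seed=seed)
    base.update(overrides)
    return SimConfig(**base)


def _one_dataset(n: int, m: int, seed: int, trait_model: TraitModel):
    cfg = _fast_config(n, m, seed)
    G, truth = simulate_genotypes(cfg)
    samples, true_E = simulate_covariates_exposures(cfg)
    samples, truth = simulate_phenotypes(G, samples, trait_model, seed,
                                         exposure=true_E, truth=truth)
    return G, samples, truth, true_E


def null_replicate(n: int, m: int, seed: int,
                   thresholds=DEFAULT_THRESHOLDS,
                   n_causal: int = 50) -> dict:
    """One null-cohort replicate of the full estimated-GRS procedure.

    The trait has covariate and SNP main effects but no interaction;
    returns the per-threshold interaction P-values (NaN where the
    threshold's SNP set was empty) and the combined capped P-value.
    """
    tm = TraitModel.defaults("BMI", interaction_effect=0.0,
                             n_causal=n_causal)
    G, samples, truth, true_E = _one_dataset(n, m, seed, tm)
    scan = marginal_scan(G, samples, "BMI", DEFAULT_COVARIATES, pcs=None)
    gset = build_grs_set(scan, G, thresholds, trait="BMI")

    fits = []
    p_by_thr = {}
    for t in gset.thresholds:
        if t in gset.absent:
            p_by_thr[t] = np.nan
            continue
        f = fit_interaction(samples, "BMI", gset.z[str(t)],
                            "regular_exercise", facet="overall",
                            threshold=t)
        p_by_thr[t] = f.p_int if f.estimable else np.nan
        fits.append(f)
    res = grsm_pvalue(fits, gset)
    return {"p_by_threshold": p_by_thr, "p_grsm": res.p_grsm,
            "p_min": res.p_min}


def type1_error(n_reps: int = 1000, n: int = 1000, m: int = 2000,
                seed: int = 0, reference_threshold: float = 0.05) -> dict:
    """Empirical type-I error of the interaction tests over null replicates.

    Reports the rejection rate at nominal 0.05 for a fixed single
    threshold (default the 0.05 filter, which is never empty under the
    null) and for the combined GRS-M P-value (conservative by
    construction), plus its Monte-Carlo standard error.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % 2**31)
                   for s in ss.spawn(n_reps)]
    p_single, p_grsm = [], []
    for s in child_seeds:
        rep = null_replicate(n, m, s)
        p_single.append(rep["p_by_threshold"][reference_threshold])
        p_grsm.append(rep["p_grsm"])
    p_single = np.asarray(p_single)
    p_grsm = np.asarray(p_grsm)
    ok = np.isfinite(p_single)
    rate_single = float((p_single[ok] < 0.05).mean())
    rate_grsm = float((p_grsm < 0.05).mean())
    return {
        "rate_single": rate_single,
        "rate_grsm": rate_grsm,
        "mc_se": float(np.sqrt(0.05 * 0.95 / ok.sum())),
        "n_reps": int(ok.sum()),
        "p_single": p_single,
        "p_grsm": p_grsm,
    }


def recovery_simulation(n_reps: int = 200, n: int = 2000, m: int = 200,
                        beta_int: float = -0.43, seed: int = 0,
                        trait: str = "BMI") -> dict:
    """Recovery of a generative interaction effect by model fitting.

    Each replicate simulates a cohort whose trait carries
    ``beta_int × z(burden) × E`` and fits the interaction model with the
    true standardized burden as the score, so the estimate is unbiased for
    ``beta_int`` (an estimated GRS would attenuate it by its correlation
    with the burden).  Returns the mean estimate, its empirical standard
    error over replicates, and the fraction of negative estimates.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % 2**31)
                   for s in ss.spawn(n_reps)]
    est = []
    for s in child_seeds:
        tm = TraitModel.defaults(trait, interaction_effect=beta_int,
                                 n_causal=30)
        G, samples, truth, true_E = _one_dataset(n, m, s, tm)
        f = fit_interaction(samples, trait, truth.burden[trait], true_E,
                            facet="overall", exposure_name="regular_exercise")
        if f.estimable:
            est.append(f.beta_int)
    est = np.asarray(est)
    return {
        "mean": float(est.mean()),
        "se_of_mean": float(est.std(ddof=1) / np.sqrt(est.size)),
        "frac_negative": float((est < 0).mean()),
        "n_reps": int(est.size),
        "estimates": est,
    }


def two_stage_independence(n: int = 1000, m: int = 2000, n_reps: int = 20,
                           seed: int = 0) -> dict:
    """Correlation across SNPs between marginal β̂ and interaction γ̂.

    Under the null of no SNP main effects and no interactions the two
    per-SNP estimates are asymptotically independent, so the cross-SNP
    correlation should sit within ~3/sqrt(m) of zero.  Because all m
    estimates within one cohort share a single phenotype realization, the
    single-replicate statistic is over-dispersed relative to the iid
    1/sqrt(m) scale (its spread does not shrink with n); the population
    correlation is therefore estimated by averaging over independent
    replicates, which does concentrate.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % 2**31)
                   for s in ss.spawn(n_reps)]
    cors = []
    n_used = m
    for s in child_seeds:
        tm = TraitModel.defaults("BMI", interaction_effect=0.0, n_causal=0)
        G, samples, truth, true_E = _one_dataset(n, m, s, tm)
        scan = marginal_scan(G, samples, "BMI")
        snp_int = fit_snp_interactions(G, samples, "BMI", "regular_exercise")
        both = np.isfinite(scan["beta"]) & np.isfinite(snp_int["gamma_int"])
        n_used = int(both.sum())
        cors.append(float(np.corrcoef(scan.loc[both, "beta"],
                                      snp_int.loc[both, "gamma_int"])[0, 1]))
    cors = np.asarray(cors)
    mean = float(cors.mean())
    return {"corr": mean, "abs_corr": abs(mean),
            "bound": 3.0 / np.sqrt(n_used), "n_snps": n_used,
            "per_replicate": cors, "n_reps": n_reps}
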