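"""Synthetic cohort generator.

Emulates the statistical structure a biobank-scale gene–exercise
interaction analysis assumes: LD-blocked Hardy–Weinberg genotypes with a
realistic MAF spectrum, injected duplicate and parent–offspring pairs, mild
two-subpopulation structure, questionnaire covariates, an 18-type exercise
battery (participation, monthly frequency, per-session duration) and five
obesity traits (BMI, BFP, WC, HC, WHR) generated with known SNP main effects
and a known GRS-by-exercise interaction.

All default rates, frequencies and effect sizes mirror the published cohort
descriptives; everything is overridable through :class:`SimConfig` and
:class:`TraitModel`.  A single master seed with named substreams makes every
stage independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import MISSING, GenotypeMatrix, zscore

__all__ = [
    "SimConfig", "TraitModel", "GroundTruth", "EXERCISE_TYPES",
    "simulate_genotypes", "simulate_covariates_exposures",
    "simulate_phenotypes", "simulate_cohort",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# ---------------------------------------------------------------------------
# 18 exercise types: (slug, participants-of-18424, freq/month mean, sd,
#                     duration-hours mean, sd) — cohort descriptives.
# ---------------------------------------------------------------------------
EXERCISE_TYPES = pd.DataFrame(
    [
        ("walking",            2637, 20.2, 9.6, 0.78, 0.39),
        ("exercise_walking",   1439, 18.5, 8.8, 0.81, 0.38),
        ("jogging",            1107, 14.5, 7.7, 0.70, 0.33),
        ("cycling",             989, 15.2, 9.8, 1.16, 0.89),
        ("mountain_climbing",   628,  9.0, 7.9, 1.99, 1.22),
        ("stretching",          602, 21.3, 8.4, 0.73, 0.36),
        ("intl_std_dancing",    513, 16.3, 8.2, 1.28, 0.61),
        ("swimming",            486, 15.4, 9.6, 0.84, 0.50),
        ("tai_chi",             449, 18.7, 9.5, 1.13, 0.54),
        ("ddr",                 420, 14.1, 7.7, 1.01, 0.43),
        ("yoga",                379, 11.9, 8.1, 1.17, 0.49),
        ("qigong",              377, 21.4, 9.4, 1.01, 0.46),
        ("others",              285, 18.3, 11.9, 0.96, 0.65),
        ("weight_training",     218, 15.4, 9.1, 0.80, 0.48),
        ("badminton",           204, 11.4, 6.9, 1.40, 0.60),
        ("table_tennis",        169, 15.7, 8.4, 1.34, 0.59),
        ("basketball",          119, 10.9, 7.6, 1.40, 0.68),
        ("tennis",              110, 16.7, 8.4, 1.41, 0.64),
    ],
    columns=["slug", "count", "freq_mean", "freq_sd", "dur_mean", "dur_sd"],
).set_index("slug")

#: probability of an exerciser reporting 1, 2 or 3 types — mean 1.45 types,
#: matching total reported participations / number of exercisers.
N_TYPES_PROBS = (0.62, 0.31, 0.07)

# Table-1-style covariate distribution parameters.
FRAC_FEMALE = 1.0 - 0.494
AGE_MEAN, AGE_SD, AGE_RANGE = 48.9, 11.0, (30.0, 70.0)
EDU_MEAN, EDU_SD = 5.46, 0.99
FRAC_DRINKING, FRAC_SMOKING = 0.073, 0.116

#: per-trait generative defaults:
#: covariate effects (sex[1=female], age, education, drinking, smoking),
#: exposure main effect, interaction effect per 1 s.d. burden, residual s.d.,
#: target trait mean.
_TRAIT_DEFAULTS = {
    "BMI": dict(covariate_effects=(-1.846, -0.001, -0.489, 0.058, 0.165),
                exposure_main_effect=-0.286, interaction_effect=-0.43,
                noise_sd=3.52, mean=24.31),
    "BFP": dict(covariate_effects=(8.472, 0.007, -0.876, 0.487, 0.608),
                exposure_main_effect=-0.813, interaction_effect=-0.62,
                noise_sd=5.90, mean=27.29),
    "WC":  dict(covariate_effects=(-7.141, 0.089, -1.279, 0.702, 0.942),
                exposure_main_effect=-1.242, interaction_effect=-0.70,
                noise_sd=9.21, mean=83.93),
    "HC":  dict(covariate_effects=(-2.590, -0.070, -0.436, -0.031, -0.091),
                exposure_main_effect=-0.644, interaction_effect=-0.70,
                noise_sd=6.73, mean=96.34),
    "WHR": dict(covariate_effects=(-0.0505, 0.0016, -0.0092, 0.0078, 0.0101),
                exposure_main_effect=-0.0067, interaction_effect=-0.001,
                noise_sd=0.059, mean=0.87),
}

# named substreams off the master seed, so stages regenerate independently
_STREAMS = {"genotypes": 0, "relatives": 1, "hwe": 2, "missing": 3,
            "covariates": 4, "phenotypes": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],))
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------
@dataclass
class SimConfig:
    """Knobs of the synthetic cohort; the defaults are the study conditions."""

    n_samples: int = 2000
    n_snps: int = 5000
    block_size: int = 50
    within_block_corr: float = 0.8
    maf_range: tuple = (0.01, 0.5)
    frac_low_maf: float = 0.02
    frac_hwe_violating: float = 0.0
    missing_rate_range: tuple = (0.0, 0.02)
    n_duplicate_pairs: int = 2
    n_po_pairs: int = 2
    n_subpops: int = 2
    subpop_divergence: float = 0.01
    frac_regular_exercise: float = 0.415
    n_exposure_nonresponse: int = 8
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2 or self.n_snps < 1:
            raise ConfigError("need n_samples >= 2 and n_snps >= 1")
        if self.block_size < 1:
            raise ConfigError("block_size must be >= 1")
        if not (0.0 <= self.within_block_corr < 1.0):
            raise ConfigError("within_block_corr must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must satisfy 0 < low <= high <= 0.5")
        for name in ("frac_low_maf", "frac_hwe_violating",
                     "frac_regular_exercise"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be a proportion in [0, 1]")
        mlo, mhi = self.missing_rate_range
        if not (0.0 <= mlo <= mhi <= 1.0):
            raise ConfigError("missing_rate_range must be within [0, 1]")
        if self.n_subpops < 1:
            raise ConfigError("n_subpops must be >= 1")
        if self.subpop_divergence < 0:
            raise ConfigError("subpop_divergence must be >= 0")
        n_rel = 2 * (self.n_duplicate_pairs + self.n_po_pairs)
        if n_rel > self.n_samples:
            raise ConfigError("too many relative pairs for n_samples")


@dataclass
class TraitModel:
    """Generative model of one quantitative trait.

    ``interaction_effect`` is the trait change, per 1 s.d. of the true
    genetic burden, associated with being an exerciser — the quantity the
    downstream interaction model estimates.
    """

    trait_name: str = "BMI"
    covariate_effects: tuple = _TRAIT_DEFAULTS["BMI"]["covariate_effects"]
    n_causal: int = 50
    causal_effect_sd: float = 1.0
    target_genetic_r2: float = 0.02
    exposure_main_effect: float = _TRAIT_DEFAULTS["BMI"]["exposure_main_effect"]
    interaction_effect: float = _TRAIT_DEFAULTS["BMI"]["interaction_effect"]
    noise_sd: float = _TRAIT_DEFAULTS["BMI"]["noise_sd"]
    mean: float = _TRAIT_DEFAULTS["BMI"]["mean"]

    @classmethod
    def defaults(cls, trait_name: str, **overrides) -> "TraitModel":
        if trait_name not in _TRAIT_DEFAULTS:
            raise ConfigError(f"unknown trait {trait_name!r}")
        return cls(trait_name=trait_name, **{**_TRAIT_DEFAULTS[trait_name],
                                             **overrides})

    def validate(self) -> None:
        if not (0.0 <= self.target_genetic_r2 < 1.0):
            raise ConfigError("target_genetic_r2 must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.n_causal < 0:
            raise ConfigError("n_causal must be >= 0")


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline is asked to recover."""

    subpop: np.ndarray = None
    duplicate_pairs: list = field(default_factory=list)   # expected PI-HAT 1
    po_pairs: list = field(default_factory=list)          # expected PI-HAT 0.5
    hwe_violating_snps: list = field(default_factory=list)
    true_maf: np.ndarray = None
    regular_exercise: np.ndarray = None   # pre-nonresponse exposure
    causal_snps: dict = field(default_factory=dict)       # trait -> DataFrame
    burden: dict = field(default_factory=dict)            # trait -> z-scored


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------
def _ar1_latent(rng, n_draws: int, n_snps: int, block_size: int,
                rho: float) -> np.ndarray:
    """Latent N(0,1) field with AR(1) correlation within consecutive blocks."""
    z = rng.standard_normal((n_draws, n_snps))
    if rho == 0.0 or block_size <= 1:
        return z
    innov = np.sqrt(1.0 - rho * rho)
    for j in range(1, n_snps):
        if j % block_size == 0:     # block boundary: restart the chain
            continue
        z[:, j] = rho * z[:, j - 1] + innov * z[:, j]
    return z


def simulate_genotypes(config: SimConfig):
    """Draw the genotype matrix and its ground truth.

    Two haplotypes per sample per SNP come from a thresholded latent-Gaussian
    copula with AR(1) within-block correlation, so Hardy–Weinberg holds by
    construction; a configurable SNP subset then has its heterozygotes
    thinned to half their expected count (the excess-homozygosity signature
    of genotyping error).  Duplicate pairs are genotype-row copies (with
    independent missingness); parent–offspring pairs share exactly one
    haplotype.
    """
    config.validate()
    n, m = config.n_samples, config.n_snps
    rng = _rng(config.seed, "genotypes")

    # MAF spectrum, with a low-frequency tail below 1%
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    low = rng.random(m) < config.frac_low_maf
    maf[low] = rng.uniform(0.001, 0.01, size=low.sum())

    # subpopulation allele frequencies (Balding–Nichols around the base MAF)
    subpop = rng.integers(0, config.n_subpops, size=n)
    F = config.subpop_divergence
    if config.n_subpops > 1 and F > 0:
        a = maf * (1.0 - F) / F
        b = (1.0 - maf) * (1.0 - F) / F
        freqs = rng.beta(a, b, size=(config.n_subpops, m))
        freqs = np.clip(freqs, 1e-4, 1.0 - 1e-4)
    else:
        freqs = np.tile(maf, (config.n_subpops, 1))

    # threshold the latent field at the upper-tail allele frequency
    thresh = stats.norm.isf(freqs)              # (n_subpops, m)
    z = _ar1_latent(rng, 2 * n, m, config.block_size,
                    config.within_block_corr).reshape(n, 2, m)
    hap = (z > thresh[subpop][:, None, :]).astype(np.int8)

    truth = GroundTruth(subpop=subpop, true_maf=maf)

    # parent–offspring pairs: child shares haplotype 0 with the parent,
    # haplotype 1 is an independent draw already in place
    rng_rel = _rng(config.seed, "relatives")
    n_rel = 2 * (config.n_duplicate_pairs + config.n_po_pairs)
    rel_idx = rng_rel.choice(n, size=n_rel, replace=False) if n_rel else []
    pos = 0
    for _ in range(config.n_po_pairs):
        parent, child = rel_idx[pos], rel_idx[pos + 1]
        pos += 2
        hap[child, 0, :] = hap[parent, 0, :]
        truth.po_pairs.append((int(parent), int(child)))

    geno = hap.sum(axis=1).astype(np.int8)

    # heterozygote thinning: resample hets to half their expected count
    rng_hwe = _rng(config.seed, "hwe")
    if config.frac_hwe_violating > 0:
        n_bad = int(round(config.frac_hwe_violating * m))
        bad = rng_hwe.choice(m, size=n_bad, replace=False)
        for j in bad:
            hets = np.where(geno[:, j] == 1)[0]
            flip = hets[rng_hwe.random(hets.size) < 0.5]
            to_hom2 = rng_hwe.random(flip.size) < maf[j]
            geno[flip, j] = np.where(to_hom2, 2, 0).astype(np.int8)
        truth.hwe_violating_snps = sorted(int(j) for j in bad)

    # duplicates: exact genotype-row copies (missingness applied later)
    for _ in range(config.n_duplicate_pairs):
        src, dst = rel_idx[pos], rel_idx[pos + 1]
        pos += 2
        geno[dst, :] = geno[src, :]
        truth.duplicate_pairs.append((int(src), int(dst)))

    # per-SNP missingness, uniform at random within each SNP
    rng_miss = _rng(config.seed, "missing")
    lo, hi = config.missing_rate_range
    if hi > 0:
        rate = rng_miss.uniform(lo, hi, size=m)
        mask = rng_miss.random((n, m)) < rate
        geno[mask] = MISSING

    # SNP metadata: one synthetic chromosome per 10 blocks, A1 = minor
    bases = np.array(["A", "C", "G", "T"])
    a1 = bases[rng.integers(0, 4, size=m)]
    a2 = bases[(np.char.find("ACGT", a1) + 1 + rng.integers(0, 3, size=m)) % 4]
    snps_per_chrom = max(config.block_size * 10, 1)
    chrom = 1 + np.arange(m) // snps_per_chrom
    pos_bp = 1 + (np.arange(m) % snps_per_chrom) * 1000
    snps = pd.DataFrame(
        {"chrom": chrom, "pos": pos_bp, "a1": a1, "a2": a2},
        index=pd.Index([f"rs{j:06d}" for j in range(m)], name="snp_id"),
    )
    G = GenotypeMatrix(geno, snps)
    return G, truth


# ---------------------------------------------------------------------------
# covariates and exposures
# ---------------------------------------------------------------------------
def simulate_covariates_exposures(config: SimConfig, n: int | None = None):
    """Draw the questionnaire table: covariates and the exercise battery.

    Returns ``(samples, truth_exposure)`` where ``samples`` is a DataFrame
    with columns ``sex`` (1 = female), ``age``, ``education`` (1–7),
    ``drinking``, ``smoking``, ``regular_exercise`` and, per exercise type
    ``t``, ``ex_t`` (0/1 participation), ``freq_t`` (sessions/month) and
    ``dur_t`` (hours/session); non-participants carry zeros.  A configurable
    handful of rows has all exposure columns set to NaN (questionnaire
    non-response); ``truth_exposure`` is the pre-masking overall indicator.
    """
    config.validate()
    n = config.n_samples if n is None else int(n)
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = _rng(config.seed, "covariates")

    sex = (rng.random(n) < FRAC_FEMALE).astype(int)
    a, b = (AGE_RANGE[0] - AGE_MEAN) / AGE_SD, (AGE_RANGE[1] - AGE_MEAN) / AGE_SD
    age = stats.truncnorm.rvs(a, b, loc=AGE_MEAN, scale=AGE_SD, size=n,
                              random_state=rng)
    education = np.clip(np.rint(rng.normal(EDU_MEAN, EDU_SD, size=n)),
                        1, 7).astype(int)
    drinking = (rng.random(n) < FRAC_DRINKING).astype(int)
    smoking = (rng.random(n) < FRAC_SMOKING).astype(int)
    exercise = (rng.random(n) < config.frac_regular_exercise).astype(int)

    samples = pd.DataFrame({
        "sex": sex, "age": age, "education": education,
        "drinking": drinking, "smoking": smoking,
        "regular_exercise": exercise.astype(float),
    }, index=pd.Index([f"S{i:06d}" for i in range(n)], name="sample_id"))

    slugs = EXERCISE_TYPES.index.to_numpy()
    part = np.zeros((n, len(slugs)), dtype=float)
    ex_idx = np.where(exercise == 1)[0]
    if ex_idx.size:
        k = rng.choice([1, 2, 3], size=ex_idx.size, p=N_TYPES_PROBS)
        # Gumbel-top-k: exact weighted sampling without replacement
        w = EXERCISE_TYPES["count"].to_numpy(dtype=float)
        keys = np.log(w)[None, :] + rng.gumbel(size=(ex_idx.size, len(slugs)))
        order = np.argsort(-keys, axis=1)
        for rank in range(3):
            rows = ex_idx[k > rank]
            part[rows, order[k > rank, rank]] = 1.0

    freq = np.zeros_like(part)
    dur = np.zeros_like(part)
    for j, slug in enumerate(slugs):
        rowsel = part[:, j] == 1
        cnt = int(rowsel.sum())
        if cnt == 0:
            continue
        fm, fs = EXERCISE_TYPES.loc[slug, ["freq_mean", "freq_sd"]]
        dm, ds = EXERCISE_TYPES.loc[slug, ["dur_mean", "dur_sd"]]
        fa, fb = (1.0 - fm) / fs, (60.0 - fm) / fs
        freq[rowsel, j] = np.rint(stats.truncnorm.rvs(
            fa, fb, loc=fm, scale=fs, size=cnt, random_state=rng))
        da, db = (0.1 - dm) / ds, (6.0 - dm) / ds
        dur[rowsel, j] = stats.truncnorm.rvs(
            da, db, loc=dm, scale=ds, size=cnt, random_state=rng)

    for j, slug in enumerate(slugs):
        samples[f"ex_{slug}"] = part[:, j]
        samples[f"freq_{slug}"] = freq[:, j]
        samples[f"dur_{slug}"] = dur[:, j]

    truth_exposure = exercise.astype(float).copy()
    n_nr = min(config.n_exposure_nonresponse, n)
    if n_nr > 0:
        nr = rng.choice(n, size=n_nr, replace=False)
        expo_cols = ["regular_exercise"] + [
            f"{p}_{s}" for s in slugs for p in ("ex", "freq", "dur")]
        samples.loc[samples.index[nr], expo_cols] = np.nan
    return samples, truth_exposure


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------
def simulate_phenotypes(G: GenotypeMatrix, samples: pd.DataFrame,
                        tm: TraitModel, seed: int,
                        exposure: np.ndarray | None = None,
                        truth: GroundTruth | None = None):
    """Fill one trait column from its generative model.

    trait = intercept + covariate effects + scaled causal-SNP burden
            + beta_E * E + beta_Int * z(burden) * E + N(0, noise_sd),

    with the causal component scaled so its variance share relative to the
    non-genetic part equals ``target_genetic_r2``.  ``exposure`` defaults to
    the (pre-nonresponse) overall regular-exercise indicator.
    """
    tm.validate()
    if G.n_samples != len(samples):
        raise ValueError(
            f"genotypes have {G.n_samples} samples but table has {len(samples)}"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(
            _STREAMS["phenotypes"],
            zlib.crc32(tm.trait_name.encode()) % 2**31,
        ))
    )
    n = len(samples)
    if exposure is None:
        exposure = samples["regular_exercise"].to_numpy(dtype=float)
        exposure = np.where(np.isnan(exposure), 0.0, exposure)
    E = np.asarray(exposure, dtype=float)

    C = samples[["sex", "age", "education", "drinking", "smoking"]].to_numpy(float)
    cov_part = C @ np.asarray(tm.covariate_effects, dtype=float)
    noise = rng.normal(0.0, tm.noise_sd, size=n)
    nongenetic = cov_part + tm.exposure_main_effect * E + noise

    burden = np.zeros(n)
    genetic = np.zeros(n)
    causal = pd.DataFrame(columns=["effect"])
    if tm.n_causal > 0:
        idx = rng.choice(G.n_snps, size=min(tm.n_causal, G.n_snps),
                         replace=False)
        effects = rng.normal(0.0, tm.causal_effect_sd, size=idx.size)
        raw = G.dosages(impute=True)[:, idx] @ effects
        if raw.std() > 0:
            burden = zscore(raw)
            if tm.target_genetic_r2 > 0:
                r2 = tm.target_genetic_r2
                target_var = r2 / (1.0 - r2) * nongenetic.var()
                genetic = (raw - raw.mean()) * np.sqrt(target_var) / raw.std()
        causal = pd.DataFrame({"effect": effects},
                              index=G.snp_ids[idx].rename("snp_id"))

    trait = nongenetic + genetic + tm.interaction_effect * burden * E
    trait += tm.mean - trait.mean()

    out = samples.copy()
    out[tm.trait_name] = trait
    if truth is None:
        truth = GroundTruth()
    truth.causal_snps[tm.trait_name] = causal
    truth.burden[tm.trait_name] = burden
    return out, truth


def simulate_cohort(config: SimConfig, trait_models=None):
    """End-to-end synthesis: genotypes, covariates/exposures and all traits.

    Returns ``(G, samples, truth)``.  ``trait_models`` defaults to the five
    obesity measures with their published-default generative parameters.
    """
    if trait_models is None:
        trait_models = [TraitModel.defaults(t) for t in _TRAIT_DEFAULTS]
    G, truth = simulate_genotypes(config)
    samples, true_E = simulate_covariates_exposures(config)
    truth.regular_exercise = true_E
    for tm in trait_models:
        samples, truth = simulate_phenotypes(
            G, samples, tm, config.seed, exposure=true_E, truth=truth)
    return G, samples, truth
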