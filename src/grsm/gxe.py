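"""GRS-by-exposure interaction inference.

The centrepiece is the two-stage procedure: for one trait and one exposure,
the interaction model

    trait ~ GRS + E + GRS×E + covariates [+ co-exposure terms]

is fitted at each of the 10 marginal-filter thresholds, and the combined
P-value is 10 × the minimum of the single-threshold interaction P-values,
capped at 1 (Bonferroni over the grid).  The per-SNP interaction scan, the
exposure main-effect model (no GRS terms), stratified GRS effects and
quartile summaries round out the analysis; ``run_analysis_matrix``
enumerates the full 5-trait × 55-exposure matrix (275 interaction + 275
main-effect tests) with study-wide significance at 0.05/550.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import DEFAULT_COVARIATES, TRAITS, GenotypeMatrix
from .grs import DEFAULT_THRESHOLDS, build_grs_set, covariate_design, marginal_scan
from .linmod import Residualizer, ols
from .simulate import EXERCISE_TYPES

__all__ = [
    "ALPHA_STUDY", "InteractionFit", "GRSMResult", "AnalysisMatrix",
    "fit_interaction", "fit_main_effect", "fit_snp_interactions",
    "grsm_pvalue", "stratified_grs_effect", "quartile_summary",
    "exposure_definitions", "run_analysis_matrix",
]

log = logging.getLogger(__name__)

#: study-wide significance level: 275 interaction + 275 main-effect tests
ALPHA_STUDY = 0.05 / 550


@dataclass
class InteractionFit:
    trait: str
    exposure: str
    facet: str
    threshold: float | None
    beta_grs: float = np.nan
    se_grs: float = np.nan
    p_grs: float = np.nan
    beta_e: float = np.nan
    se_e: float = np.nan
    p_e: float = np.nan
    beta_int: float = np.nan
    se_int: float = np.nan
    p_int: float = np.nan
    n: int = 0
    estimable: bool = False
    note: str = ""


@dataclass
class GRSMResult:
    trait: str
    exposure: str
    facet: str
    p_min: float
    p_grsm: float
    argmin_threshold: float
    n_snps_argmin: int
    beta_int_argmin: float
    n_fits: int
    significant: bool


def _series(samples: pd.DataFrame, x, name: str) -> pd.Series:
    if isinstance(x, str):
        return samples[x].rename(name)
    return pd.Series(np.asarray(x, dtype=float), index=samples.index,
                     name=name)


def _interaction_design(samples, grs, E, covariates, pcs, co_exposures):
    """Complete-case design for the interaction model; returns (y-mask, X,
    names) builder pieces shared by interaction and main-effect fits."""
    frames = [E]
    if co_exposures is not None:
        frames.append(co_exposures)
    if grs is not None:
        frames.append(grs)
    aux = pd.concat(frames, axis=1)
    cc = samples[list(covariates)].notna().all(axis=1) & aux.notna().all(axis=1)
    return cc


def fit_interaction(samples: pd.DataFrame, trait: str, grs, exposure,
                    covariates=DEFAULT_COVARIATES,
                    pcs: pd.DataFrame | None = None,
                    co_exposures: pd.DataFrame | None = None,
                    facet: str = "overall", exposure_name: str | None = None,
                    threshold: float | None = None) -> InteractionFit:
    """Fit trait ~ GRS + E + GRS×E + covariates [+ co-exposure terms].

    ``co_exposures`` (one column per other exercise type, on the same facet
    as the focal exposure) enter both as plain covariates and as GRS×column
    interaction terms.  Rows with a missing trait, covariate, exposure or
    co-exposure are dropped (complete-case); a rank-deficient design is
    flagged inestimable rather than raising.
    """
    grs = _series(samples, grs, "GRS")
    E = _series(samples, exposure, "E")
    exposure_name = exposure_name or (exposure if isinstance(exposure, str)
                                      else "E")
    cc = _interaction_design(samples, grs, E, covariates, pcs, co_exposures)
    cc &= samples[trait].notna()
    sub = samples.loc[cc]
    y = sub[trait].to_numpy(dtype=float)
    X0, names = covariate_design(sub, covariates, pcs)

    cols = [X0]
    g = grs.loc[cc].to_numpy()
    e = E.loc[cc].to_numpy()
    n_const = 0
    if co_exposures is not None:
        C = co_exposures.loc[cc].to_numpy(dtype=float)
        # constant co-exposure columns (e.g. a type with no participants in
        # this subsample) carry no information: drop them, don't void the fit
        keep = C.std(axis=0) > 0
        n_const = int((~keep).sum())
        C = C[:, keep]
        co_names = [c for c, k in zip(co_exposures.columns, keep) if k]
        cols.append(C)
        names += [f"co_{c}" for c in co_names]
        cols.append(C * g[:, None])
        names += [f"GRSx_co_{c}" for c in co_names]
    cols.append(np.column_stack([g, e, g * e]))
    names += ["GRS", "E", "GRSxE"]
    X = np.column_stack(cols)

    fit = ols(y, X, names)
    out = InteractionFit(trait=trait, exposure=exposure_name, facet=facet,
                         threshold=threshold, n=fit.n, estimable=fit.estimable)
    if n_const:
        out.note = f"dropped {n_const} constant co-exposure column(s)"
    if not fit.estimable:
        out.note = "rank-deficient design"
        log.info("fit_interaction(%s, %s/%s, t=%s): inestimable",
                 trait, exposure_name, facet, threshold)
        return out
    for key, prefix in (("GRS", "grs"), ("E", "e"), ("GRSxE", "int")):
        d = fit[key]
        setattr(out, f"beta_{prefix}", float(d["coef"]))
        setattr(out, f"se_{prefix}", float(d["se"]))
        setattr(out, f"p_{prefix}", float(d["p"]))
    return out


def fit_main_effect(samples: pd.DataFrame, trait: str, exposure,
                    covariates=DEFAULT_COVARIATES,
                    pcs: pd.DataFrame | None = None,
                    co_exposures: pd.DataFrame | None = None,
                    facet: str = "overall",
                    exposure_name: str | None = None) -> InteractionFit:
    """Exposure main-effect model: trait ~ E + covariates [+ co-exposures].

    No GRS or interaction terms.  The result reuses :class:`InteractionFit`
    with only the E fields populated (threshold None).
    """
    E = _series(samples, exposure, "E")
    exposure_name = exposure_name or (exposure if isinstance(exposure, str)
                                      else "E")
    cc = _interaction_design(samples, None, E, covariates, pcs, co_exposures)
    cc &= samples[trait].notna()
    sub = samples.loc[cc]
    y = sub[trait].to_numpy(dtype=float)
    X0, names = covariate_design(sub, covariates, pcs)
    cols = [X0]
    if co_exposures is not None:
        C = co_exposures.loc[cc].to_numpy(dtype=float)
        keep = C.std(axis=0) > 0
        cols.append(C[:, keep])
        names += [f"co_{c}" for c, k in zip(co_exposures.columns, keep) if k]
    cols.append(E.loc[cc].to_numpy()[:, None])
    names += ["E"]
    fit = ols(y, np.column_stack(cols), names)

    out = InteractionFit(trait=trait, exposure=exposure_name, facet=facet,
                         threshold=None, n=fit.n, estimable=fit.estimable)
    if not fit.estimable:
        out.note = "rank-deficient design"
        return out
    d = fit["E"]
    out.beta_e, out.se_e, out.p_e = float(d["coef"]), float(d["se"]), float(d["p"])
    return out


def grsm_pvalue(fits, grs_set=None, alpha: float = ALPHA_STUDY) -> GRSMResult:
    """Combine the per-threshold interaction tests into the GRS-M P-value.

    GRS-M P = min(1, 10 × min single-threshold P).  The multiplier stays 10
    even when some thresholds were absent or inestimable (conservative).
    """
    usable = [f for f in fits if f.estimable and np.isfinite(f.p_int)]
    if not usable:
        raise ValueError("no estimable single-threshold fit; GRS-M undefined")
    best = min(usable, key=lambda f: f.p_int)
    p_grsm = min(1.0, 10.0 * best.p_int)
    n_snps = grs_set.n_snps(best.threshold) if grs_set is not None else -1
    return GRSMResult(
        trait=best.trait, exposure=best.exposure, facet=best.facet,
        p_min=best.p_int, p_grsm=p_grsm, argmin_threshold=best.threshold,
        n_snps_argmin=n_snps, beta_int_argmin=best.beta_int,
        n_fits=len(usable), significant=bool(p_grsm < alpha))


def fit_snp_interactions(G: GenotypeMatrix, samples: pd.DataFrame, trait: str,
                         exposure, covariates=DEFAULT_COVARIATES,
                         pcs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-SNP interaction scan: trait ~ SNP + E + SNP×E + covariates.

    Vectorized across SNPs by residualizing the trait, the dosage and the
    dosage×E product on the base design (intercept, covariates, PCs, E) and
    solving the remaining 2×2 normal equations per SNP.  Returns a
    DataFrame with the SNP main term ``beta_snp`` and the interaction term
    ``gamma_int`` (plus ``se``, ``p``, ``n``) per SNP.
    """
    E = _series(samples, exposure, "E")
    used = [trait, *covariates]
    cc = (samples[used].notna().all(axis=1) & E.notna()).to_numpy()
    sub = samples.loc[cc]
    y = sub[trait].to_numpy(dtype=float)
    e = E.loc[cc].to_numpy(dtype=float)
    X0, _ = covariate_design(sub, covariates, pcs)
    X0 = np.column_stack([X0, e])

    D = G.dosages(impute=True)[cc, :]
    resid = Residualizer(X0)
    yt = resid(y)
    Dt = resid(D)
    Et = resid(D * e[:, None])

    a = np.einsum("ij,ij->j", Dt, Dt)
    b = np.einsum("ij,ij->j", Dt, Et)
    c = np.einsum("ij,ij->j", Et, Et)
    u = Dt.T @ yt
    v = Et.T @ yt
    det = a * c - b * b
    ok = det > 1e-10 * len(y)

    beta = np.full(G.n_snps, np.nan)
    gamma = np.full(G.n_snps, np.nan)
    se = np.full(G.n_snps, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta[ok] = (c[ok] * u[ok] - b[ok] * v[ok]) / det[ok]
        gamma[ok] = (a[ok] * v[ok] - b[ok] * u[ok]) / det[ok]
    df = len(y) - resid.rank - 2
    rss = float(yt @ yt) - beta * u - gamma * v
    sigma2 = np.maximum(rss, 0.0) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        se[ok] = np.sqrt(sigma2[ok] * a[ok] / det[ok])
        tval = gamma / se
    pval = 2.0 * stats.t.sf(np.abs(tval), df)
    return pd.DataFrame({"beta_snp": beta, "gamma_int": gamma, "se": se,
                         "t": tval, "p": pval, "n": len(y)}, index=G.snp_ids)


def stratified_grs_effect(samples: pd.DataFrame, trait: str, grs, strata,
                          covariates=DEFAULT_COVARIATES,
                          pcs: pd.DataFrame | None = None,
                          min_size: int = 30) -> pd.DataFrame:
    """Per-stratum OLS of trait on GRS + covariates.

    ``strata`` maps each sample to a group label (a Series or array);
    strata smaller than ``min_size`` are flagged but still reported when
    estimable.
    """
    grs = _series(samples, grs, "GRS")
    strata = pd.Series(np.asarray(strata), index=samples.index)
    rows = []
    for label in strata.dropna().unique():
        mask = (strata == label) & samples[trait].notna() & grs.notna() \
            & samples[list(covariates)].notna().all(axis=1)
        sub = samples.loc[mask]
        flag = "small_stratum" if mask.sum() < min_size else ""
        if mask.sum() == 0:
            rows.append((label, np.nan, np.nan, np.nan, 0, "empty_stratum"))
            continue
        X0, names = covariate_design(sub, covariates, pcs)
        X = np.column_stack([X0, grs.loc[mask].to_numpy()[:, None]])
        fit = ols(sub[trait].to_numpy(dtype=float), X, names + ["GRS"])
        if not fit.estimable:
            rows.append((label, np.nan, np.nan, np.nan, fit.n,
                         (flag + ";" if flag else "") + "inestimable"))
            continue
        d = fit["GRS"]
        rows.append((label, d["coef"], d["se"], d["p"], fit.n, flag))
    return pd.DataFrame(rows, columns=["stratum", "beta_grs", "se", "p",
                                       "n", "flag"]).set_index("stratum")


def quartile_summary(grs, exposure, trait) -> pd.DataFrame:
    """Mean trait per (GRS quartile × exposure level), with Δ(Q4 − Q1).

    Quartiles cut at the 25/50/75 percentiles with ties assigned to the
    lower quartile.  Returns a 5-row frame (Q1..Q4 plus ``delta``) with one
    column per exposure level.
    """
    grs = np.asarray(grs, dtype=float)
    trait = np.asarray(trait, dtype=float)
    exposure = np.asarray(exposure)
    if np.unique(grs[np.isfinite(grs)]).size < 4:
        raise ValueError("GRS needs at least 4 distinct values for quartiles")
    c1, c2, c3 = np.percentile(grs, [25, 50, 75])
    q = 1 + (grs > c1).astype(int) + (grs > c2).astype(int) \
        + (grs > c3).astype(int)

    levels = pd.unique(exposure[~pd.isna(exposure)])
    out = pd.DataFrame(index=[f"Q{k}" for k in range(1, 5)] + ["delta"],
                       columns=levels, dtype=float)
    for lev in levels:
        sel = exposure == lev
        for k in range(1, 5):
            out.loc[f"Q{k}", lev] = trait[sel & (q == k)].mean() \
                if (sel & (q == k)).any() else np.nan
        out.loc["delta", lev] = out.loc["Q4", lev] - out.loc["Q1", lev]
    return out


# ---------------------------------------------------------------------------
# the full analysis matrix
# ---------------------------------------------------------------------------
def exposure_definitions(include_overall: bool = True) -> list:
    """The 55 exposure definitions: overall participation plus
    {participation, monthly frequency, per-session duration} × 18 types.

    Each entry is ``(name, facet, column, co_columns)`` where ``co_columns``
    are the same-facet columns of the other 17 types (None for overall).
    """
    defs = []
    if include_overall:
        defs.append(("regular_exercise", "overall", "regular_exercise", None))
    slugs = list(EXERCISE_TYPES.index)
    for prefix, facet in (("ex", "participation"), ("freq", "frequency"),
                          ("dur", "duration")):
        for s in slugs:
            co = [f"{prefix}_{o}" for o in slugs if o != s]
            defs.append((s, facet, f"{prefix}_{s}", co))
    return defs


@dataclass
class AnalysisMatrix:
    interactions: pd.DataFrame
    mains: pd.DataFrame
    alpha_study: float
    grs_sets: dict = field(default_factory=dict, repr=False)

    @property
    def n_interaction_tests(self) -> int:
        return len(self.interactions)

    @property
    def n_main_effect_tests(self) -> int:
        return len(self.mains)

    @property
    def n_total_tests(self) -> int:
        return self.n_interaction_tests + self.n_main_effect_tests

    def summary_table(self, facet: str) -> pd.DataFrame:
        """Wide per-exposure table for one facet: β̂_Int and GRS-M P per
        trait (the published tables' layout)."""
        sub = self.interactions[self.interactions["facet"] == facet]
        parts = []
        for trait, grp in sub.groupby("trait"):
            g = grp.set_index("exposure")
            parts.append(pd.DataFrame({
                (trait, "beta_int"): g["beta_int_argmin"],
                (trait, "grsm_p"): g["p_grsm"],
                (trait, "n_snps"): g["n_snps_argmin"],
            }))
        return pd.concat(parts, axis=1)


def run_analysis_matrix(G: GenotypeMatrix, samples: pd.DataFrame,
                        pcs: pd.DataFrame | None = None,
                        traits=TRAITS, thresholds=DEFAULT_THRESHOLDS,
                        covariates=DEFAULT_COVARIATES,
                        alpha_study: float = ALPHA_STUDY,
                        scans: dict | None = None,
                        grs_sets: dict | None = None) -> AnalysisMatrix:
    """Enumerate all trait × exposure tests with study-wide significance.

    One marginal scan (and one threshold grid of scores) per trait is
    reused across all 55 exposure definitions, as the two-stage procedure
    prescribes.  Inestimable entries are retained with NaN statistics and a
    note so the enumeration count is always complete.
    """
    missing_cols = [c for c in ("regular_exercise",)
                    if c not in samples.columns]
    if missing_cols:
        raise KeyError(f"samples table lacks exposure column(s): {missing_cols}")

    scans = dict(scans or {})
    grs_sets = dict(grs_sets or {})
    for trait in traits:
        if trait not in scans:
            scans[trait] = marginal_scan(G, samples, trait, covariates, pcs)
        if trait not in grs_sets:
            grs_sets[trait] = build_grs_set(scans[trait], G, thresholds,
                                            trait=trait)

    defs = exposure_definitions()
    for name, facet, col, co in defs:
        if col not in samples.columns:
            raise KeyError(f"samples table lacks exposure column {col!r}")

    int_rows, main_rows = [], []
    for trait in traits:
        gset = grs_sets[trait]
        for name, facet, col, co in defs:
            co_df = samples[co] if co else None
            fits = []
            for t in gset.thresholds:
                if t in gset.absent:
                    continue
                fits.append(fit_interaction(
                    samples, trait, gset.z[str(t)], col, covariates, pcs,
                    co_df, facet=facet, exposure_name=name, threshold=t))
            try:
                res = grsm_pvalue(fits, gset, alpha_study)
                int_rows.append(dict(
                    trait=trait, exposure=name, facet=facet,
                    beta_int_argmin=res.beta_int_argmin, p_min=res.p_min,
                    p_grsm=res.p_grsm, argmin_threshold=res.argmin_threshold,
                    n_snps_argmin=res.n_snps_argmin, n_fits=res.n_fits,
                    significant=res.significant, note=""))
            except ValueError as err:
                int_rows.append(dict(
                    trait=trait, exposure=name, facet=facet,
                    beta_int_argmin=np.nan, p_min=np.nan, p_grsm=np.nan,
                    argmin_threshold=np.nan, n_snps_argmin=0, n_fits=0,
                    significant=False, note=str(err)))

            m = fit_main_effect(samples, trait, col, covariates, pcs,
                                co_df, facet=facet, exposure_name=name)
            main_rows.append(dict(
                trait=trait, exposure=name, facet=facet, beta_e=m.beta_e,
                se_e=m.se_e, p_e=m.p_e, n=m.n,
                significant=bool(np.isfinite(m.p_e) and m.p_e < alpha_study),
                note=m.note))

    return AnalysisMatrix(interactions=pd.DataFrame(int_rows),
                          mains=pd.DataFrame(main_rows),
                          alpha_study=alpha_study, grs_sets=grs_sets)
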