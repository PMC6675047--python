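"""Interaction inference: OLS identities, the statsmodels oracle, the
Bonferroni-over-thresholds combination, stratified effects, quartile
summaries and the full analysis-matrix enumeration."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from grsm.data import TRAITS
from grsm.gxe import (ALPHA_STUDY, InteractionFit, exposure_definitions,
                      fit_interaction, fit_main_effect, fit_snp_interactions,
                      grsm_pvalue, quartile_summary, run_analysis_matrix,
                      stratified_grs_effect)
from grsm.simulate import (SimConfig, TraitModel, simulate_covariates_exposures,
                           simulate_genotypes, simulate_phenotypes)


@pytest.fixture(scope="module")
def cohort():
    cfg = SimConfig(n_samples=600, n_snps=150, seed=51, n_subpops=1,
                    within_block_corr=0.0, n_duplicate_pairs=0, n_po_pairs=0,
                    missing_rate_range=(0.0, 0.0), n_exposure_nonresponse=0)
    G, truth = simulate_genotypes(cfg)
    samples, true_E = simulate_covariates_exposures(cfg)
    tm = TraitModel.defaults("BMI", n_causal=10, interaction_effect=-0.8)
    samples, truth = simulate_phenotypes(G, samples, tm, cfg.seed,
                                         exposure=true_E, truth=truth)
    return G, samples, truth, true_E


class TestFitInteraction:
    def test_matches_statsmodels_oracle(self, cohort):
        G, samples, truth, true_E = cohort
        grs = truth.burden["BMI"]
        fit = fit_interaction(samples, "BMI", grs, "regular_exercise")
        C = samples[["sex", "age", "education", "drinking",
                     "smoking"]].to_numpy(float)
        E = samples["regular_exercise"].to_numpy()
        X = sm.add_constant(np.column_stack([C, grs, E, grs * E]))
        ref = sm.OLS(samples["BMI"].to_numpy(), X).fit()
        assert fit.beta_int == pytest.approx(ref.params[-1], abs=1e-10)
        assert fit.se_int == pytest.approx(ref.bse[-1], abs=1e-10)
        assert fit.p_int == pytest.approx(ref.pvalues[-1], abs=1e-10)
        assert fit.beta_grs == pytest.approx(ref.params[-3], abs=1e-10)
        assert fit.beta_e == pytest.approx(ref.params[-2], abs=1e-10)

    def test_covariate_free_group_slope_identity(self, cohort):
        # with no covariates and binary E, beta_int equals the difference of
        # within-group slopes of trait on GRS
        _, samples, truth, _ = cohort
        grs = truth.burden["BMI"]
        fit = fit_interaction(samples, "BMI", grs, "regular_exercise",
                              covariates=())
        y = samples["BMI"].to_numpy()
        E = samples["regular_exercise"].to_numpy()
        slopes = {}
        for e in (0, 1):
            g = grs[E == e]
            yy = y[E == e]
            slopes[e] = np.polyfit(g, yy, 1)[0]
        assert fit.beta_int == pytest.approx(slopes[1] - slopes[0],
                                             abs=1e-10)

    def test_constant_exposure_inestimable(self, cohort):
        _, samples, truth, _ = cohort
        const_E = np.ones(len(samples))
        fit = fit_interaction(samples, "BMI", truth.burden["BMI"], const_E)
        assert not fit.estimable

    def test_co_exposure_terms_enter_design(self, cohort):
        _, samples, truth, _ = cohort
        co = samples[["ex_walking", "ex_cycling"]]
        fit = fit_interaction(samples, "BMI", truth.burden["BMI"],
                              "ex_jogging", co_exposures=co,
                              facet="participation")
        assert fit.estimable
        # oracle with the same design
        cc = samples
        C = cc[["sex", "age", "education", "drinking",
                "smoking"]].to_numpy(float)
        g = truth.burden["BMI"]
        E = cc["ex_jogging"].to_numpy()
        Cx = co.to_numpy(float)
        X = sm.add_constant(np.column_stack(
            [C, Cx, Cx * g[:, None], g, E, g * E]))
        ref = sm.OLS(cc["BMI"].to_numpy(), X).fit()
        assert fit.beta_int == pytest.approx(ref.params[-1], abs=1e-10)


class TestGrsmPvalue:
    @staticmethod
    def _fit(p, t):
        return InteractionFit(trait="BMI", exposure="regular_exercise",
                              facet="overall", threshold=t, p_int=p,
                              beta_int=-0.1, estimable=True, n=100)

    def test_times_ten(self):
        res = grsm_pvalue([self._fit(0.002, 0.05)])
        assert res.p_grsm == pytest.approx(0.02)

    def test_capped_at_one(self):
        res = grsm_pvalue([self._fit(0.5, 0.05)])
        assert res.p_grsm == 1.0

    def test_all_equal(self):
        fits = [self._fit(0.004, t) for t in (0.01, 0.025, 0.05)]
        assert grsm_pvalue(fits).p_grsm == pytest.approx(0.04)

    def test_argmin_threshold_recorded(self):
        fits = [self._fit(0.03, 0.01), self._fit(0.001, 0.05)]
        res = grsm_pvalue(fits)
        assert res.argmin_threshold == 0.05
        assert res.p_min == pytest.approx(0.001)

    def test_no_estimable_fit_raises(self):
        bad = InteractionFit(trait="BMI", exposure="x", facet="overall",
                             threshold=0.05, estimable=False)
        with pytest.raises(ValueError):
            grsm_pvalue([bad])


class TestSnpInteractions:
    def test_matches_statsmodels_oracle(self, cohort):
        G, samples, truth, _ = cohort
        res = fit_snp_interactions(G, samples, "BMI", "regular_exercise")
        C = samples[["sex", "age", "education", "drinking",
                     "smoking"]].to_numpy(float)
        E = samples["regular_exercise"].to_numpy()
        y = samples["BMI"].to_numpy()
        D = G.dosages()
        for j in (0, 50, 149):
            X = sm.add_constant(np.column_stack(
                [C, E, D[:, j], D[:, j] * E]))
            ref = sm.OLS(y, X).fit()
            assert res["gamma_int"].iloc[j] == pytest.approx(ref.params[-1],
                                                             abs=1e-10)
            assert res["se"].iloc[j] == pytest.approx(ref.bse[-1], abs=1e-10)
            assert res["beta_snp"].iloc[j] == pytest.approx(ref.params[-2],
                                                            abs=1e-10)

    def test_interacting_snp_attains_minimum_p(self):
        cfg = SimConfig(n_samples=2500, n_snps=150, seed=53, n_subpops=1,
                        within_block_corr=0.0, n_duplicate_pairs=0,
                        n_po_pairs=0, missing_rate_range=(0.0, 0.0))
        G, truth = simulate_genotypes(cfg)
        samples, true_E = simulate_covariates_exposures(cfg)
        tm = TraitModel.defaults("BMI", n_causal=1, target_genetic_r2=0.0,
                                 interaction_effect=-3.0)
        samples, truth = simulate_phenotypes(G, samples, tm, cfg.seed,
                                             exposure=true_E, truth=truth)
        res = fit_snp_interactions(G, samples, "BMI", "regular_exercise")
        assert res["p"].idxmin() == truth.causal_snps["BMI"].index[0]


class TestMainEffect:
    def test_recovers_generative_effect(self):
        # overall-exercise main effect on BMI, generative default -0.286
        est, ses = [], []
        for s in range(25):
            cfg = SimConfig(n_samples=2000, n_snps=20, seed=100 + s,
                            n_subpops=1, within_block_corr=0.0,
                            n_duplicate_pairs=0, n_po_pairs=0,
                            missing_rate_range=(0.0, 0.0),
                            n_exposure_nonresponse=0)
            G, truth = simulate_genotypes(cfg)
            samples, true_E = simulate_covariates_exposures(cfg)
            tm = TraitModel.defaults("BMI", n_causal=0,
                                     interaction_effect=0.0)
            samples, _ = simulate_phenotypes(G, samples, tm, cfg.seed,
                                             exposure=true_E, truth=truth)
            f = fit_main_effect(samples, "BMI", "regular_exercise")
            est.append(f.beta_e)
        mean = np.mean(est)
        se = np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(mean - (-0.286)) < 3 * se + 1e-12

    def test_constant_exposure_flagged(self, cohort):
        _, samples, _, _ = cohort
        f = fit_main_effect(samples, "BMI", np.ones(len(samples)))
        assert not f.estimable


class TestStratified:
    def test_identity_with_interaction_model(self, cohort):
        _, samples, truth, _ = cohort
        grs = truth.burden["BMI"]
        strata = samples["regular_exercise"].map({0.0: "none", 1.0: "any"})
        res = stratified_grs_effect(samples, "BMI", grs, strata,
                                    covariates=())
        fit = fit_interaction(samples, "BMI", grs, "regular_exercise",
                              covariates=())
        diff = res.loc["any", "beta_grs"] - res.loc["none", "beta_grs"]
        assert diff == pytest.approx(fit.beta_int, abs=1e-10)
        assert res.loc["none", "beta_grs"] == pytest.approx(fit.beta_grs,
                                                            abs=1e-10)

    def test_attenuation_detected(self, cohort):
        _, samples, truth, _ = cohort
        grs = truth.burden["BMI"]    # generative interaction -0.8
        strata = samples["regular_exercise"].map({0.0: "inactive",
                                                  1.0: "active"})
        res = stratified_grs_effect(samples, "BMI", grs, strata)
        assert res.loc["active", "beta_grs"] < res.loc["inactive", "beta_grs"]

    def test_small_stratum_flagged(self, cohort):
        _, samples, truth, _ = cohort
        strata = pd.Series("big", index=samples.index)
        strata.iloc[:10] = "tiny"
        res = stratified_grs_effect(samples, "BMI", truth.burden["BMI"],
                                    strata)
        assert res.loc["tiny", "flag"].startswith("small_stratum")


class TestQuartiles:
    def test_trait_equal_to_grs(self, rng):
        grs = rng.normal(size=400)
        E = rng.integers(0, 2, 400)
        out = quartile_summary(grs, E, grs)
        q = np.percentile(grs, [25, 75])
        for lev in (0, 1):
            sel = E == lev
            assert out.loc["delta", lev] == pytest.approx(
                grs[sel & (grs > q[1])].mean()
                - grs[sel & (grs <= q[0])].mean())

    def test_balanced_cell_counts(self, rng):
        grs = rng.permutation(np.arange(400).astype(float))
        E = np.zeros(400)
        c1, c2, c3 = np.percentile(grs, [25, 50, 75])
        q = 1 + (grs > c1) + (grs > c2) + (grs > c3)
        assert [int((q == k).sum()) for k in range(1, 5)] == [100] * 4

    def test_attenuation_visible_in_delta(self, cohort):
        _, samples, truth, _ = cohort
        grs = truth.burden["BMI"]
        E = samples["regular_exercise"].to_numpy()
        out = quartile_summary(grs, E, samples["BMI"].to_numpy())
        assert out.loc["delta", 1.0] < out.loc["delta", 0.0]

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError):
            quartile_summary(np.array([1.0, 1.0, 2.0, 2.0]),
                             np.zeros(4), np.zeros(4))


class TestAnalysisMatrix:
    def test_enumeration_counts(self):
        defs = exposure_definitions()
        assert len(defs) == 55
        facets = pd.Series([d[1] for d in defs]).value_counts()
        assert facets["participation"] == 18
        assert facets["frequency"] == 18
        assert facets["duration"] == 18
        assert facets["overall"] == 1

    def test_full_matrix_shape_and_alpha(self, cohort):
        G, samples, _, _ = cohort
        for t in TRAITS:
            if t not in samples:
                tm = TraitModel.defaults(t, n_causal=5,
                                         interaction_effect=0.0)
                samples, _ = simulate_phenotypes(G, samples, tm, 51)
        am = run_analysis_matrix(G, samples)
        assert am.n_interaction_tests == 275
        assert am.n_main_effect_tests == 275
        assert am.n_total_tests == 550
        assert am.alpha_study == pytest.approx(0.05 / 550)
        assert ALPHA_STUDY == pytest.approx(9.1e-5, rel=5e-3)
        wide = am.summary_table("participation")
        assert wide.shape[0] == 18

    def test_missing_exposure_column_raises(self, cohort):
        G, samples, _, _ = cohort
        bad = samples.drop(columns=["freq_jogging"])
        with pytest.raises(KeyError, match="freq_jogging"):
            run_analysis_matrix(G, bad, traits=("BMI",))
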