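"""Internal-weight GRS construction: marginal scan against a statsmodels
oracle, threshold-grid membership, z-scoring, and external-weight scores."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from grsm.data import GenotypeMatrix, zscore
from grsm.grs import (DEFAULT_THRESHOLDS, build_external_grs, build_grs_set,
                      marginal_scan)
from grsm.simulate import (SimConfig, TraitModel, simulate_covariates_exposures,
                           simulate_genotypes, simulate_phenotypes)


@pytest.fixture(scope="module")
def scan_cohort():
    cfg = SimConfig(n_samples=400, n_snps=120, seed=41, n_subpops=1,
                    within_block_corr=0.0, n_duplicate_pairs=0, n_po_pairs=0,
                    missing_rate_range=(0.0, 0.0), n_exposure_nonresponse=0)
    G, truth = simulate_genotypes(cfg)
    samples, true_E = simulate_covariates_exposures(cfg)
    tm = TraitModel.defaults("BMI", n_causal=5, target_genetic_r2=0.15,
                             interaction_effect=0.0)
    samples, truth = simulate_phenotypes(G, samples, tm, cfg.seed,
                                         exposure=true_E, truth=truth)
    return G, samples, truth


class TestMarginalScan:
    def test_matches_statsmodels_oracle(self, scan_cohort):
        G, samples, _ = scan_cohort
        scan = marginal_scan(G, samples, "BMI")
        C = samples[["sex", "age", "education", "drinking",
                     "smoking"]].to_numpy(float)
        y = samples["BMI"].to_numpy()
        D = G.dosages()
        for j in [0, 7, 33, 119]:
            X = sm.add_constant(np.column_stack([C, D[:, j]]))
            ref = sm.OLS(y, X).fit()
            assert scan["beta"].iloc[j] == pytest.approx(ref.params[-1],
                                                         abs=1e-10)
            assert scan["se"].iloc[j] == pytest.approx(ref.bse[-1],
                                                       abs=1e-10)
            assert scan["p"].iloc[j] == pytest.approx(ref.pvalues[-1],
                                                      abs=1e-10)

    def test_causal_snp_attains_minimum_p(self):
        cfg = SimConfig(n_samples=1500, n_snps=200, seed=43, n_subpops=1,
                        within_block_corr=0.0, n_duplicate_pairs=0,
                        n_po_pairs=0, missing_rate_range=(0.0, 0.0))
        G, truth = simulate_genotypes(cfg)
        samples, true_E = simulate_covariates_exposures(cfg)
        tm = TraitModel.defaults("BMI", n_causal=1, target_genetic_r2=0.1,
                                 interaction_effect=0.0)
        samples, truth = simulate_phenotypes(G, samples, tm, cfg.seed,
                                             exposure=true_E, truth=truth)
        scan = marginal_scan(G, samples, "BMI")
        causal_id = truth.causal_snps["BMI"].index[0]
        assert scan["p"].idxmin() == causal_id

    def test_null_pvalues_uniform(self):
        cfg = SimConfig(n_samples=800, n_snps=1000, seed=47, n_subpops=1,
                        within_block_corr=0.0, n_duplicate_pairs=0,
                        n_po_pairs=0, missing_rate_range=(0.0, 0.0))
        G, truth = simulate_genotypes(cfg)
        samples, true_E = simulate_covariates_exposures(cfg)
        tm = TraitModel.defaults("BMI", n_causal=0, interaction_effect=0.0,
                                 exposure_main_effect=0.0)
        samples, _ = simulate_phenotypes(G, samples, tm, cfg.seed,
                                         exposure=true_E, truth=truth)
        scan = marginal_scan(G, samples, "BMI")
        from scipy.stats import kstest
        assert kstest(scan["p"].dropna(), "uniform").pvalue > 0.01

    def test_zero_variance_snp_skipped(self, scan_cohort):
        G, samples, _ = scan_cohort
        g = G.genotypes.copy()
        g[:, 5] = 1
        G2 = GenotypeMatrix(g, G.snps)
        scan = marginal_scan(G2, samples, "BMI")
        assert np.isnan(scan["beta"].iloc[5])
        assert scan["beta"].drop(scan.index[5]).notna().all()


class TestGrsSet:
    def test_threshold_one_includes_all(self, scan_cohort):
        G, samples, _ = scan_cohort
        scan = marginal_scan(G, samples, "BMI")
        gset = build_grs_set(scan, G, thresholds=(1.0,))
        assert len(gset.members[1.0]) == G.n_snps

    def test_toy_grid_membership_counts(self, scan_cohort):
        G, _, _ = scan_cohort
        G3 = G.subset_snps(G.snp_ids[:3])
        scan = pd.DataFrame(
            {"beta": [0.5, -0.2, 0.1], "se": 1.0, "t": 0.0,
             "p": [0.0002, 0.03, 0.2], "n": 100}, index=G3.snp_ids)
        gset = build_grs_set(scan, G3)
        counts = tuple(gset.n_snps(t) for t in DEFAULT_THRESHOLDS)
        # p=0.0002 enters at t=0.00025; p=0.03 at t=0.05; p=0.2 never
        assert counts == (0, 1, 1, 1, 1, 1, 1, 1, 2, 2)

    def test_nested_members_and_z_normalization(self, scan_cohort):
        G, samples, _ = scan_cohort
        scan = marginal_scan(G, samples, "BMI")
        gset = build_grs_set(scan, G, trait="BMI")
        for t1, t2 in zip(gset.thresholds, gset.thresholds[1:]):
            assert set(gset.members[t1]) <= set(gset.members[t2])
            assert len(gset.members[t1]) <= len(gset.members[t2])
        for t in gset.thresholds:
            if t in gset.absent:
                continue
            z = gset.z[str(t)].to_numpy()
            assert abs(z.mean()) < 1e-10
            assert abs(z.std() - 1.0) < 1e-10

    def test_weights_are_scan_betas_bit_for_bit(self, scan_cohort):
        G, samples, _ = scan_cohort
        scan = marginal_scan(G, samples, "BMI")
        gset = build_grs_set(scan, G)
        for t in gset.thresholds:
            for sid, w in gset.weights[t].items():
                assert w == scan.loc[sid, "beta"]

    def test_non_increasing_grid_rejected(self, scan_cohort):
        G, samples, _ = scan_cohort
        scan = marginal_scan(G, samples, "BMI")
        with pytest.raises(ValueError):
            build_grs_set(scan, G, thresholds=(0.05, 0.05))


class TestExternalGrs:
    def _weights(self, G, rows):
        return pd.DataFrame(rows, columns=["snp_id", "effect_allele",
                                           "weight"])

    def test_single_weight_equals_standardized_dosage(self, scan_cohort):
        G, _, _ = scan_cohort
        sid = G.snp_ids[4]
        a1 = G.snps.loc[sid, "a1"]
        w = self._weights(G, [(sid, a1, 1.0)])
        score, report = build_external_grs(G, w)
        expect = zscore(G.dosages()[:, 4])
        assert np.allclose(score.to_numpy(), expect, atol=1e-12)
        assert report == {"matched": 1, "allele_mismatch": 0, "unmatched": 0}

    def test_flipped_effect_allele_negates_score(self, scan_cohort):
        G, _, _ = scan_cohort
        sid = G.snp_ids[4]
        a1, a2 = G.snps.loc[sid, ["a1", "a2"]]
        s1, _ = build_external_grs(G, self._weights(G, [(sid, a1, 1.0)]))
        s2, _ = build_external_grs(G, self._weights(G, [(sid, a2, 1.0)]))
        assert np.allclose(s1.to_numpy(), -s2.to_numpy(), atol=1e-12)

    def test_zero_weights_error(self, scan_cohort):
        G, _, _ = scan_cohort
        sid = G.snp_ids[0]
        w = self._weights(G, [(sid, G.snps.loc[sid, "a1"], 0.0)])
        with pytest.raises(ValueError, match="zero variance"):
            build_external_grs(G, w)

    def test_no_match_error(self, scan_cohort):
        G, _, _ = scan_cohort
        w = self._weights(G, [("rs_nowhere", "A", 1.0)])
        with pytest.raises(ValueError, match="no external weight"):
            build_external_grs(G, w)

    def test_weights_tsv_round_trip(self, scan_cohort, tmp_path):
        from grsm.grs import read_external_weights
        G, _, _ = scan_cohort
        sid = G.snp_ids[4]
        path = tmp_path / "weights.tsv"
        path.write_text("snp_id\teffect_allele\tweight\n"
                        f"{sid}\t{G.snps.loc[sid, 'a1']}\t0.37\n")
        w = read_external_weights(path)
        score, report = build_external_grs(G, w)
        assert report["matched"] == 1
        with pytest.raises(ValueError, match="lacks columns"):
            bad = tmp_path / "bad.tsv"
            bad.write_text("snp\tw\nx\t1\n")
            read_external_weights(bad)

    def test_unmatched_weights_reported(self, scan_cohort):
        G, _, _ = scan_cohort
        sid = G.snp_ids[4]
        w = self._weights(G, [(sid, G.snps.loc[sid, "a1"], 0.3),
                              ("rs_nowhere", "A", 0.5)])
        _, report = build_external_grs(G, w)
        assert report["unmatched"] == 1
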