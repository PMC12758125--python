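"""Ground-truth generator: genotypes, protein, outcome, scans, weights."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ciswas.synthetic_cohort import (ConfigError, ScenarioConfig, fit_weights,
                                     make_sumstats, make_variants,
                                     scenario_config, simulate_genotypes,
                                     simulate_outcome, simulate_protein,
                                     simulate_scenario)


def _cfg(**kw):
    base = dict(regime="shared_causal", seed=1)
    base.update(kw)
    return ScenarioConfig(**base)


class TestGenotypes:
    def test_mean_dosage_matches_hwe(self):
        cfg = _cfg(seed=5, n_variants=5, maf_range=(0.5, 0.5))
        dos, _, _ = simulate_genotypes(cfg, n=10_000)
        assert np.allclose(dos.mean(axis=0), 1.0, atol=0.02)

    def test_determinism(self):
        cfg = _cfg(seed=11, n_variants=10)
        d1, l1, v1 = simulate_genotypes(cfg, n=500)
        d2, l2, v2 = simulate_genotypes(cfg, n=500)
        assert np.array_equal(d1, d2)
        assert np.array_equal(l1.r, l2.r)
        pd.testing.assert_frame_equal(v1, v2)

    def test_adjacent_ld_matches_copula_oracle(self):
        # oracle: the thresholded-copula correlation of two HWE dosages,
        # corr = (Phi2(t_i, t_j, rho) - m_i m_j) / sqrt(prod m(1-m)),
        # evaluated with the bivariate normal CDF (attenuated below rho)
        maf = 0.3
        rho = 0.8
        cfg = _cfg(seed=21, n_variants=6, maf_range=(maf, maf), ld_decay=rho)
        dos, ld, _ = simulate_genotypes(cfg, n=10_000)
        t = stats.norm.ppf(maf)
        p11 = stats.multivariate_normal(cov=[[1, rho], [rho, 1]]).cdf([t, t])
        expected = (p11 - maf ** 2) / (maf * (1 - maf))
        adjacent = np.array([ld.r[i, i + 1] for i in range(5)])
        assert expected < rho  # attenuation is real and documented
        assert np.allclose(adjacent, expected, atol=0.05)

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            _cfg(n_variants=1)
        with pytest.raises(ConfigError):
            _cfg(maf_range=(0.0, 0.5))
        with pytest.raises(ConfigError):
            _cfg(prevalence=1.5)
        with pytest.raises(ConfigError):
            ScenarioConfig(regime="bogus", seed=1)


class TestProtein:
    def test_heritability_recovered_by_regression(self):
        cfg = _cfg(seed=31, n_variants=30, h2_protein=0.3, n_causal=5)
        rng = np.random.default_rng(cfg.seed)
        dos, _, _ = simulate_genotypes(cfg, n=20_000, rng=rng)
        protein, w = simulate_protein(dos, cfg, rng=rng)
        causal = np.flatnonzero(w)
        x = np.column_stack([np.ones(len(protein)), dos[:, causal]])
        coef, res, *_ = np.linalg.lstsq(x, protein, rcond=None)
        r2 = 1 - res[0] / (len(protein) * protein.var())
        assert r2 == pytest.approx(0.3, abs=0.03)

    def test_null_heritability_gives_zero_weights_and_r2(self):
        cfg = _cfg(seed=41, n_variants=10, h2_protein=0.0, n_causal=3)
        rng = np.random.default_rng(cfg.seed)
        dos, _, _ = simulate_genotypes(cfg, n=20_000, rng=rng)
        protein, w = simulate_protein(dos, cfg, rng=rng)
        assert np.all(w == 0)
        x = np.column_stack([np.ones(len(protein)), dos])
        _, res, *_ = np.linalg.lstsq(x, protein, rcond=None)
        assert 1 - res[0] / (len(protein) * protein.var()) < 0.005

    def test_single_causal_correlation_is_sqrt_h2(self):
        cfg = _cfg(seed=51, n_variants=5, h2_protein=0.5, n_causal=1)
        rng = np.random.default_rng(cfg.seed)
        dos, _, _ = simulate_genotypes(cfg, n=20_000, rng=rng)
        protein, w = simulate_protein(dos, cfg, rng=rng)
        j = int(np.flatnonzero(w)[0])
        r = np.corrcoef(protein, dos[:, j])[0, 1]
        assert abs(r) == pytest.approx(np.sqrt(0.5), abs=0.03)


class TestOutcome:
    def test_sample_prevalence_matches_config(self):
        cfg = _cfg(seed=61, prevalence=0.1)
        rng = np.random.default_rng(cfg.seed)
        protein = rng.standard_normal(20_000)
        outcome, _, _ = simulate_outcome(protein, cfg, rng=rng)
        assert outcome.mean() == pytest.approx(0.1, abs=0.01)

    def test_all_null_betas_give_independent_outcome(self):
        import statsmodels.api as sm
        cfg = _cfg(seed=71, beta_protein_on_outcome=0.0)
        rng = np.random.default_rng(cfg.seed)
        protein = rng.standard_normal(20_000)
        outcome, _, _ = simulate_outcome(protein, cfg, rng=rng)
        fit = sm.Logit(outcome, sm.add_constant(protein)).fit(disp=0)
        assert abs(fit.params[1]) < 2.5 * fit.bse[1]

    def test_mediated_ground_truth_proportion_exact(self):
        cfg = scenario_config("mediated", seed=81)
        rng = np.random.default_rng(cfg.seed)
        protein = rng.standard_normal(5000)
        _, _, truth = simulate_outcome(protein, cfg, rng=rng,
                                       mediator_genetic=np.zeros(5000))
        assert truth.true_proportion_mediated == pytest.approx(0.25)
        assert truth.true_indirect_effect == pytest.approx(0.3 * 0.25)
        assert truth.true_total_effect == pytest.approx(0.225 + 0.075)


class TestMakeSumstats:
    def test_null_type1_calibration(self):
        # 500 unlinked variants, outcome independent of all of them
        cfg = _cfg(seed=91, n_variants=500, ld_decay=0.0)
        rng = np.random.default_rng(cfg.seed)
        dos, _, variants = simulate_genotypes(cfg, n=3000, rng=rng)
        y = rng.standard_normal(3000)
        ss = make_sumstats(dos, y, "quantitative", variants, "null")
        frac = (ss.records["p"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_causal_variant_attains_smallest_p(self):
        cfg = _cfg(seed=101, n_variants=40, h2_protein=0.5, n_causal=1)
        rng = np.random.default_rng(cfg.seed)
        dos, _, variants = simulate_genotypes(cfg, n=5000, rng=rng)
        protein, w = simulate_protein(dos, cfg, rng=rng)
        ss = make_sumstats(dos, protein, "quantitative", variants, "pqtl")
        best = ss.records.loc[ss.records["p"].idxmin(), "variant_id"]
        causal = variants["variant_id"].iloc[int(np.flatnonzero(w)[0])]
        assert best == causal

    def test_monomorphic_variant_flagged(self):
        cfg = _cfg(seed=111, n_variants=3)
        rng = np.random.default_rng(cfg.seed)
        dos, _, variants = simulate_genotypes(cfg, n=200, rng=rng)
        dos[:, 1] = 0.0
        y = rng.standard_normal(200)
        ss = make_sumstats(dos, y, "quantitative", variants, "t")
        assert ss.records.loc[1, "flag"] == "monomorphic"
        assert not np.isfinite(ss.records.loc[1, "se"])

    def test_binary_uses_balanced_case_control_sample(self):
        cfg = _cfg(seed=121, prevalence=0.2, n_variants=5)
        rng = np.random.default_rng(cfg.seed)
        dos, _, variants = simulate_genotypes(cfg, n=4000, rng=rng)
        y = (rng.random(4000) < 0.2).astype(int)
        ss = make_sumstats(dos, y, "binary", variants, "cc", rng=rng)
        assert (ss.records["n"] == 2 * y.sum()).all()
        assert (ss.records["n_cases"] == y.sum()).all()


class TestFitWeights:
    def test_top1_recovers_single_causal_variant(self):
        hits = 0
        for s in range(20):
            cfg = _cfg(seed=200 + s, n_variants=30, h2_protein=0.4,
                       n_causal=1)
            rng = np.random.default_rng(cfg.seed)
            dos, _, variants = simulate_genotypes(cfg, n=2000, rng=rng)
            protein, w = simulate_protein(dos, cfg, rng=rng)
            ws = fit_weights(dos, protein, variants, models=("top1",),
                             seed=cfg.seed)
            causal = variants["variant_id"].iloc[int(np.flatnonzero(w)[0])]
            hits += ws.entries["variant_id"].iloc[0] == causal
        assert hits >= 17  # >= 90% nominal, binomial slack at 20 seeds

    def test_enet_beats_top1_with_two_spread_causals(self):
        wins = 0
        for s in range(15):
            cfg = _cfg(seed=300 + s, n_variants=30, h2_protein=0.4,
                       n_causal=2, ld_decay=0.1)
            rng = np.random.default_rng(cfg.seed)
            dos, _, variants = simulate_genotypes(cfg, n=2000, rng=rng)
            # two equally weighted causal SNPs in low LD, far apart
            w = np.zeros(30)
            idx = np.array([5, 25])
            g = dos[:, idx] @ np.ones(2)
            w[idx] = np.sqrt(cfg.h2_protein) / g.std()
            protein, _ = simulate_protein(dos, cfg, rng=rng, causal_idx=idx,
                                          weights=w)
            ws = fit_weights(dos, protein, variants, seed=cfg.seed)
            wins += ws.model_tag == "enet"
        assert wins >= 11  # enet preferred in >= ~80% of replicates

    def test_fewer_individuals_than_folds_rejected(self):
        cfg = _cfg(seed=1, n_variants=3)
        rng = np.random.default_rng(1)
        dos, _, variants = simulate_genotypes(cfg, n=3, rng=rng)
        with pytest.raises(ConfigError):
            fit_weights(dos, np.zeros(3), variants, k_folds=5)

    def test_top1_weightset_has_single_entry(self):
        cfg = _cfg(seed=401, n_variants=10, h2_protein=0.3, n_causal=1)
        rng = np.random.default_rng(cfg.seed)
        dos, _, variants = simulate_genotypes(cfg, n=1000, rng=rng)
        protein, _ = simulate_protein(dos, cfg, rng=rng)
        ws = fit_weights(dos, protein, variants, models=("top1",), seed=1)
        assert ws.model_tag == "top1" and len(ws.entries) == 1


class TestScenario:
    def test_scenario_determinism(self):
        cfg = scenario_config("shared_causal", seed=42, n_individuals=1500,
                              n_pqtl=800, n_variants=15)
        b1 = simulate_scenario(cfg)
        b2 = simulate_scenario(cfg)
        pd.testing.assert_frame_equal(b1.gwas.records, b2.gwas.records)
        pd.testing.assert_frame_equal(b1.pqtl.records, b2.pqtl.records)
        pd.testing.assert_frame_equal(b1.weights.entries, b2.weights.entries)
        assert np.array_equal(b1.ld.r, b2.ld.r)

    def test_shared_causal_pwas_sign_matches_planted_effect(self,
                                                            shared_bundle):
        from ciswas.xwas import assoc_z
        res = assoc_z(shared_bundle.weights, shared_bundle.gwas,
                      shared_bundle.ld)
        assert np.sign(res.z_assoc) == np.sign(
            shared_bundle.config.beta_protein_on_outcome)
        assert abs(res.z_assoc) > 3

    def test_mediated_scenario_has_mediator_gwas_and_block_ld(
            self, mediated_bundle):
        b = mediated_bundle
        assert b.mediator_gwas is not None
        assert len(b.ld.variant_ids) == len(b.variants)
        assert set(b.gwas.records["chromosome"]) == {"1", "2"}

    def test_scenario_round_trips_through_files(self, tmp_path):
        from ciswas.synthetic_cohort import write_scenario
        from ciswas.sumstats_io import read_sumstats
        cfg = scenario_config("shared_causal", seed=7, n_individuals=1200,
                              n_pqtl=700, n_variants=12)
        b = simulate_scenario(cfg, gene_id="g1")
        write_scenario(b, tmp_path)
        gwas = read_sumstats(tmp_path / "gwas.tsv", trait_type="binary")
        assert len(gwas) == len(b.gwas.records)
        assert (tmp_path / "truth.json").exists()
        assert (tmp_path / "ld" / "g1.ids").exists()
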