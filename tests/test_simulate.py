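"""Simulator: genotypes, effects, phenotypes, scans, experiments."""

import numpy as np
import pandas as pd
import pytest

from gxelder import (
    SimulationConfig,
    association_scan,
    draw_effects,
    make_panel,
    prs_by_e_check,
    run_experiment,
    simulate_genotypes,
    simulate_phenotype,
    simulate_study,
    summarize_experiment,
)


class TestConfigValidation:
    def test_variance_budget_enforced(self):
        with pytest.raises(ValueError, match="exceed"):
            SimulationConfig(h2g=0.9, h2i=0.2)

    def test_correlations_bounded(self):
        with pytest.raises(ValueError):
            SimulationConfig(r_ig=1.5)

    def test_non_psd_effect_correlation_rejected(self):
        with pytest.raises(ValueError, match="PSD"):
            SimulationConfig(heritable_e=True, h2e=0.3, h2i=0.02,
                             r_ig=0.9, r_ge=0.9, r_ie=-0.9)

    def test_causal_count_floor(self):
        with pytest.raises(ValueError, match="causal"):
            SimulationConfig(m=10, causal_fraction=0.01)

    def test_rho_ig_identity(self):
        cfg = SimulationConfig(h2g=0.2, h2i=0.02, r_ig=0.5)
        np.testing.assert_allclose(cfg.rho_ig, np.sqrt(0.2 * 0.02) * 0.5)


class TestGenotypes:
    def test_identity_profile_is_uncorrelated(self):
        cfg = SimulationConfig(n=5000, m=40, n_blocks=4, ld="identity")
        G, _ = simulate_genotypes(cfg, np.random.default_rng(0))
        R = np.corrcoef(G.T)
        off = R[~np.eye(40, dtype=bool)]
        assert np.all(np.abs(off) < 4 / np.sqrt(5000) * 1.5)

    def test_ar1_adjacent_correlation(self):
        cfg = SimulationConfig(n=5000, m=100, n_blocks=1, ld="ar1",
                               ld_param=0.9, ld_param_min=0.9)
        G, _ = simulate_genotypes(cfg, np.random.default_rng(1))
        adj = np.array([np.corrcoef(G[:, j], G[:, j + 1])[0, 1] for j in range(99)])
        assert abs(adj.mean() - 0.9) < 0.05

    def test_standardized_columns(self):
        cfg = SimulationConfig(n=500, m=60, n_blocks=3)
        G, assignment = simulate_genotypes(cfg, np.random.default_rng(2))
        np.testing.assert_allclose(G.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(G.std(axis=0), 1.0, atol=1e-12)
        assert assignment.shape == (60,)

    def test_seed_determinism(self):
        cfg = SimulationConfig(n=200, m=50, n_blocks=2)
        G1, _ = simulate_genotypes(cfg, np.random.default_rng(7))
        G2, _ = simulate_genotypes(cfg, np.random.default_rng(7))
        np.testing.assert_array_equal(G1, G2)

    def test_dosage_mode_produces_standardized_dosages(self):
        cfg = SimulationConfig(n=2000, m=40, n_blocks=2, dosage=True)
        G, _ = simulate_genotypes(cfg, np.random.default_rng(3))
        np.testing.assert_allclose(G.std(axis=0), 1.0, atol=1e-12)
        # three dosage levels per column before standardization
        assert all(len(np.unique(np.round(G[:, j], 6))) <= 3 for j in range(40))


class TestEffects:
    def test_null_interaction_effects_are_zero(self):
        cfg = SimulationConfig(h2i=0.0, r_ig=0.0)
        beta, gamma, alpha = draw_effects(cfg, np.random.default_rng(0))
        np.testing.assert_allclose(gamma, 0.0)
        assert alpha is None

    def test_causal_sparsity(self):
        cfg = SimulationConfig(m=1000, causal_fraction=0.05, h2g=0.2, h2i=0.02)
        beta, _, _ = draw_effects(cfg, np.random.default_rng(1))
        assert (beta != 0).sum() == 50

    def test_variance_budget_and_correlation(self):
        cfg = SimulationConfig(m=20_000, causal_fraction=0.05, h2g=0.2,
                               h2i=0.02, r_ig=0.5)
        rng = np.random.default_rng(4)
        beta, gamma, _ = draw_effects(cfg, rng)
        assert abs((beta**2).sum() - 0.2) < 0.03
        assert abs((gamma**2).sum() - 0.02) < 0.003
        causal = beta != 0
        r = np.corrcoef(beta[causal], gamma[causal])[0, 1]
        assert abs(r - 0.5) < 0.1

    def test_heritable_e_draws_alpha(self):
        cfg = SimulationConfig(heritable_e=True, h2e=0.3, r_ge=0.5, r_ie=0.3,
                               h2g=0.3, h2i=0.03, r_ig=0.5)
        _, _, alpha = draw_effects(cfg, np.random.default_rng(5))
        assert alpha is not None and (alpha != 0).sum() == cfg.m_causal


class TestPhenotype:
    def test_pure_noise_under_global_null(self):
        cfg = SimulationConfig(n=20_000, m=100, n_blocks=2, h2g=0.0, h2i=0.0)
        rng = np.random.default_rng(0)
        G, _ = simulate_genotypes(cfg, rng)
        beta, gamma, _ = draw_effects(cfg, rng)
        e = rng.standard_normal(cfg.n)
        y = simulate_phenotype(G, beta, gamma, e, cfg, rng)
        assert abs(y.var() - 1.0) < 0.05

    def test_variance_budget_with_signal(self):
        cfg = SimulationConfig(n=20_000, m=500, n_blocks=5, h2g=0.3,
                               h2i=0.03, r_ig=0.5)
        rng = np.random.default_rng(1)
        G, _ = simulate_genotypes(cfg, rng)
        beta, gamma, _ = draw_effects(cfg, rng)
        e = rng.standard_normal(cfg.n)
        e = (e - e.mean()) / e.std()
        y = simulate_phenotype(G, beta, gamma, e, cfg, rng)
        assert abs(y.var() - 1.0) < 0.08

    def test_non_psd_residual_covariance_rejected(self):
        # rho01 without residual-interaction variance is inconsistent
        cfg = SimulationConfig(h2g=0.2, h2i=0.0, sigma1sq=0.0, rho01=0.1,
                               n=10, m=100, n_blocks=1)
        with pytest.raises(ValueError, match="PSD"):
            simulate_phenotype(
                np.zeros((10, 100)), np.zeros(100), np.zeros(100),
                np.zeros(10), cfg, np.random.default_rng(0)
            )

    def test_heritable_environment_structure(self):
        cfg = SimulationConfig(n=20_000, m=500, n_blocks=5, h2g=0.3, h2i=0.03,
                               r_ig=0.5, heritable_e=True, h2e=0.3, r_ge=0.5,
                               r_ie=0.3)
        sim = simulate_study(cfg, 6)
        assert abs(sim.e.var() - 1.0) < 1e-9  # standardized
        genetic_part = sim.genotypes @ sim.alpha
        r = np.corrcoef(sim.e, genetic_part)[0, 1]
        assert abs(r - np.sqrt(0.3)) < 0.08


class TestAssociationScan:
    def test_null_phenotype_unit_mean_chi2(self):
        cfg = SimulationConfig(n=4000, m=600, n_blocks=6, h2g=0.0, h2i=0.0)
        rng = np.random.default_rng(2)
        G, _ = simulate_genotypes(cfg, rng)
        y = rng.standard_normal(cfg.n)
        z, n = association_scan(G, y, None, "gwas_y")
        assert n == cfg.n
        assert abs((z**2).mean() - 1.0) < 0.12

    def test_single_snp_matches_reference_ols(self):
        """The vectorized interaction scan reproduces a per-SNP OLS fit from
        an independent implementation (statsmodels)."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        n = 60
        g = rng.standard_normal((n, 1))
        g = (g - g.mean()) / g.std()
        e = rng.standard_normal(n)
        e = (e - e.mean()) / e.std()
        y = 0.3 * g[:, 0] + 0.2 * e + 0.5 * g[:, 0] * e + rng.standard_normal(n)
        z, _ = association_scan(g, y, e, "gwis_interaction")
        X = sm.add_constant(np.column_stack([g[:, 0], e, g[:, 0] * e]))
        fit = sm.OLS(y, X).fit()
        np.testing.assert_allclose(z[0], fit.tvalues[3], rtol=1e-8)
        # marginal scan against the same oracle
        z_g, _ = association_scan(g, y, None, "gwas_y")
        fit_m = sm.OLS(y, sm.add_constant(g)).fit()
        np.testing.assert_allclose(z_g[0], fit_m.tvalues[1], rtol=1e-8)

    def test_gwis_mean_chi2_without_residual_interaction(self):
        """With h2i = 0 and no residual interaction the GWIS Z² mean is ~1
        (no 2σ₁²-style inflation)."""
        cfg = SimulationConfig(n=4000, m=600, n_blocks=6, h2g=0.2, h2i=0.0)
        sim = simulate_study(cfg, 8)
        assert abs((sim.z_i**2).mean() - 1.0) < 0.12

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            association_scan(np.zeros((10, 2)), np.zeros(10), None, "bogus")


class TestExperiment:
    def test_deterministic_given_seed(self, small_cfg):
        a = run_experiment([small_cfg], replications=3, seed=5)
        b = run_experiment([small_cfg], replications=3, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_tidy_shape_and_truth_columns(self, small_cfg):
        res = run_experiment([small_cfg], replications=4, seed=6, do_baseline=True)
        assert len(res) == 4
        assert {"true_h2g", "true_h2i", "true_rho_ig", "h2g", "rho_ig",
                "rho_ig_ldsc"} <= set(res.columns)
        summary = summarize_experiment(res)
        assert len(summary) == 1
        assert summary.loc[0, "n_reps"] == 4


class TestPrsByE:
    def test_null_interaction_gives_zero_coefficient(self):
        cfg = SimulationConfig(n=4000, m=500, n_blocks=5, h2g=0.3, h2i=0.0,
                               r_ig=0.0)
        sim = simulate_study(cfg, 10)
        rec = prs_by_e_check(sim)
        assert abs(rec["beta3"]) < 0.05

    def test_oracle_prs_coefficient_matches_ratio(self):
        """Across replications, the PRS-by-E coefficient from the oracle
        (true-effect) score matches rho_ig / h2g."""
        cfg = SimulationConfig(n=3000, m=500, n_blocks=5, h2g=0.3, h2i=0.03,
                               r_ig=0.5)
        panel = make_panel(cfg, 17)
        b3 = []
        for s in range(60):
            sim = simulate_study(
                cfg, np.random.default_rng(np.random.SeedSequence([s, 2])),
                panel=panel,
            )
            b3.append(prs_by_e_check(sim)["beta3"])
        b3 = np.array(b3)
        expected = cfg.rho_ig / cfg.h2g
        mc_se = b3.std(ddof=1) / np.sqrt(len(b3))
        assert abs(b3.mean() - expected) < 3 * mc_se

    def test_noisy_prs_attenuates_toward_zero(self):
        cfg = SimulationConfig(n=3000, m=500, n_blocks=5, h2g=0.3, h2i=0.03,
                               r_ig=0.5)
        panel = make_panel(cfg, 17)
        clean, noisy = [], []
        for s in range(30):
            sim = simulate_study(
                cfg, np.random.default_rng(np.random.SeedSequence([s, 4])),
                panel=panel,
            )
            clean.append(prs_by_e_check(sim)["beta3"])
            noisy.append(
                prs_by_e_check(sim, prs_noise_sd=1.0,
                               rng=np.random.default_rng(s))["beta3"]
            )
        assert abs(np.mean(noisy)) < abs(np.mean(clean))
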