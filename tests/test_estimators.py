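"""Moment-condition estimators: noise-free inversions, oracles, invariants."""

import numpy as np
import pytest

from gxelder import (
    HarmonizedPair,
    MomentTable,
    baseline_ldsc_rho_ig,
    build_moment_table,
    compute_weights,
    estimate_all,
    estimate_h2g,
    estimate_h2i,
    estimate_rho_ig_irls,
    make_ld_reference,
    weighted_moment_regression,
)

M, N_G, N_I = 1000, 2000.0, 2000.0


def make_table(d, products, block_ids=None, M=M, n_g=N_G, n_i=N_I):
    d = np.asarray(d, float)
    if block_ids is None:
        block_ids = np.zeros(d.shape, int)
        block_ids[len(d) // 2:] = 1
    return MomentTable(
        d=d, block_ids=np.asarray(block_ids), products=products,
        M=M, n_g=n_g, n_i=n_i,
    )


@pytest.fixture()
def d_grid(rng):
    return rng.uniform(0.2, 6.0, size=400)


class TestWeightedRegression:
    def test_exact_line_recovered(self, rng):
        x = rng.uniform(0, 5, 30)
        w = rng.uniform(0.5, 2.0, 30)
        slope, intercept = weighted_moment_regression(x, 2.0 * x + 1.0, w)
        np.testing.assert_allclose([slope, intercept], [2.0, 1.0], atol=1e-12)

    def test_flat_response(self, rng):
        x = rng.uniform(0, 5, 30)
        slope, intercept = weighted_moment_regression(x, np.full(30, 3.5), np.ones(30))
        np.testing.assert_allclose([slope, intercept], [0.0, 3.5], atol=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        x, y = rng.standard_normal((2, 50))
        w = rng.uniform(0.1, 3.0, 50)
        # brute-force weighted normal equations
        X = np.column_stack([x, np.ones(50)])
        coef = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
        slope, intercept = weighted_moment_regression(x, y, w)
        np.testing.assert_allclose([slope, intercept], coef, atol=1e-10)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            weighted_moment_regression(np.ones(5), np.arange(5.0), np.ones(5))

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            weighted_moment_regression(np.arange(5.0), np.arange(5.0), np.zeros(5))


class TestMarginalEstimators:
    def test_h2g_noise_free_inversion(self, d_grid):
        y = d_grid * N_G * 0.3 / M + 1.0
        mt = make_table(d_grid, {"gg": y})
        h2g, intercept = estimate_h2g(mt)
        np.testing.assert_allclose([h2g, intercept], [0.3, 1.0], atol=1e-10)

    def test_h2g_null_when_flat(self, d_grid):
        mt = make_table(d_grid, {"gg": np.ones_like(d_grid)})
        h2g, intercept = estimate_h2g(mt)
        np.testing.assert_allclose([h2g, intercept], [0.0, 1.0], atol=1e-12)

    def test_h2i_noise_free_inversion(self, d_grid):
        y = d_grid * N_I * 0.02 / M + 1.0 + 2.0 * (0.02 + 0.1)
        mt = make_table(d_grid, {"ii": y})
        h2i, sigma1sq, _ = estimate_h2i(mt)
        np.testing.assert_allclose([h2i, sigma1sq], [0.02, 0.1], atol=1e-10)

    def test_h2i_null(self, d_grid):
        mt = make_table(d_grid, {"ii": np.ones_like(d_grid)})
        h2i, sigma1sq, _ = estimate_h2i(mt)
        np.testing.assert_allclose([h2i, sigma1sq], [0.0, 0.0], atol=1e-12)


class TestWeights:
    def test_null_parameter_limit(self):
        d = np.array([0.5, 1.0, 4.0])
        w = compute_weights(d, 0, 0, 0, 0, 0.0, N_G, N_I, M)
        np.testing.assert_allclose(w, np.minimum(d, 1.0))

    def test_unit_eigenvalues_uniform(self):
        w = compute_weights(np.ones(5), 0, 0, 0, 0, 0.0, N_G, N_I, M)
        np.testing.assert_allclose(w, 1.0)

    def test_formula_oracle_term_by_term(self, rng):
        d = rng.uniform(0.1, 5.0, 20)
        h2g, h2i, s1, rho, a = 0.25, 0.03, 0.05, 0.02, 0.4
        w = compute_weights(d, h2g, h2i, s1, rho, a, N_G, N_I, M)
        T = (d * N_G * h2g / M + 1.0) * (
            d * N_I * h2i / M + 1.0 + 2.0 * (h2i + s1)
        ) + (np.sqrt(N_G * N_I) * rho * d / M + a) ** 2
        np.testing.assert_allclose(w, np.minimum(d, 1.0) / T, rtol=1e-12)

    def test_negative_plugins_clipped_inside_t_only(self, rng):
        d = rng.uniform(0.1, 5.0, 10)
        w_neg = compute_weights(d, -0.1, -0.02, -0.3, 0.0, 0.0, N_G, N_I, M)
        w_zero = compute_weights(d, 0.0, 0.0, 0.0, 0.0, 0.0, N_G, N_I, M)
        np.testing.assert_allclose(w_neg, w_zero)


class TestRhoIRLS:
    def test_noise_free_inversion_fast_convergence(self, d_grid):
        y = np.sqrt(N_G * N_I) * 0.05 * d_grid / M + 0.3
        mt = make_table(d_grid, {"gi": y})
        res = estimate_rho_ig_irls(mt, h2g=0.2, h2i=0.02, sigma1sq=0.0)
        np.testing.assert_allclose([res.rho_ig, res.intercept], [0.05, 0.3], atol=1e-8)
        assert res.converged and res.n_iter <= 3

    def test_null_covariance(self, d_grid):
        mt = make_table(d_grid, {"gi": np.zeros_like(d_grid)})
        res = estimate_rho_ig_irls(mt, 0.2, 0.02, 0.0)
        np.testing.assert_allclose(res.rho_ig, 0.0, atol=1e-12)

    def test_sample_overlap_invariance(self, d_grid):
        """Adding a constant to every product (the overlap channel) moves
        only the intercept, never rho_ig."""
        y = np.sqrt(N_G * N_I) * 0.03 * d_grid / M + 0.1
        r1 = estimate_rho_ig_irls(make_table(d_grid, {"gi": y}), 0.2, 0.02, 0.0)
        r2 = estimate_rho_ig_irls(make_table(d_grid, {"gi": y + 0.7}), 0.2, 0.02, 0.0)
        np.testing.assert_allclose(r2.rho_ig, r1.rho_ig, atol=1e-8)
        np.testing.assert_allclose(r2.intercept - r1.intercept, 0.7, atol=1e-8)

    def test_symmetry_in_scan_roles(self, small_cfg, small_panel):
        """Swapping the GWAS and GWIS Z vectors (and sample sizes) leaves
        rho_ig unchanged: the products are commutative."""
        from gxelder import build_moment_table, simulate_study

        sim = simulate_study(small_cfg, 3, panel=small_panel)
        pair = sim.to_pair()
        swapped = HarmonizedPair(
            variant_ids=pair.variant_ids, z_g=pair.z_i, z_i=pair.z_g,
            n_g=pair.n_i, n_i=pair.n_g,
        )
        mt1 = build_moment_table(pair, small_panel.reference.eigenblocks)
        mt2 = build_moment_table(swapped, small_panel.reference.eigenblocks)
        r1 = estimate_rho_ig_irls(mt1, 0.2, 0.02, 0.0)
        r2 = estimate_rho_ig_irls(mt2, 0.2, 0.02, 0.0)
        np.testing.assert_allclose(r1.rho_ig, r2.rho_ig, rtol=1e-10)

    def test_scale_contract(self, d_grid):
        """Doubling both sample sizes with the same underlying covariance
        doubles the product slope but leaves the implied rho_ig unchanged."""
        rho = 0.04
        y1 = np.sqrt(N_G * N_I) * rho * d_grid / M + 0.2
        y2 = np.sqrt(2 * N_G * 2 * N_I) * rho * d_grid / M + 0.2
        r1 = estimate_rho_ig_irls(make_table(d_grid, {"gi": y1}), 0.2, 0.02, 0.0)
        r2 = estimate_rho_ig_irls(
            make_table(d_grid, {"gi": y2}, n_g=2 * N_G, n_i=2 * N_I), 0.2, 0.02, 0.0
        )
        np.testing.assert_allclose(r1.rho_ig, rho, atol=1e-8)
        np.testing.assert_allclose(r2.rho_ig, rho, atol=1e-8)


class TestMomentTable:
    def test_row_count_is_sum_of_retained_ranks(self, rng):
        X = rng.standard_normal((300, 10))
        ref = make_ld_reference(X, [f"v{i}" for i in range(10)], [0] * 6 + [1] * 4)
        pair = HarmonizedPair(
            variant_ids=[f"v{i}" for i in range(10)],
            z_g=rng.standard_normal(10), z_i=rng.standard_normal(10),
            n_g=100.0, n_i=100.0,
        )
        mt = build_moment_table(pair, ref.eigenblocks)
        assert len(mt) == sum(eb.retained_rank for eb in ref.eigenblocks)

    def test_null_interaction_scan_zeroes_channels(self, rng):
        X = rng.standard_normal((300, 6))
        ref = make_ld_reference(X, list("abcdef"), [0] * 6)
        pair = HarmonizedPair(
            variant_ids=list("abcdef"), z_g=rng.standard_normal(6),
            z_i=np.zeros(6), n_g=100.0, n_i=100.0,
        )
        mt = build_moment_table(pair, ref.eigenblocks)
        np.testing.assert_allclose(mt.products["ii"], 0.0)
        np.testing.assert_allclose(mt.products["gi"], 0.0)

    def test_identity_ld_squares_match_raw(self, rng):
        """With identity LD the whitened squares are the raw Z squares (up to
        eigenvector sign/order), so the eigen estimator sees the same
        regression material as a diagonal method."""
        from gxelder import LDBlock, eigendecompose

        m = 8
        ids = [f"v{i}" for i in range(m)]
        eb = eigendecompose(LDBlock(0, ids, np.eye(m)), tol=0.0)
        z = rng.standard_normal(m)
        pair = HarmonizedPair(
            variant_ids=ids, z_g=z, z_i=z, n_g=100.0, n_i=100.0,
        )
        mt = build_moment_table(pair, [eb])
        np.testing.assert_allclose(
            np.sort(mt.products["gg"]), np.sort(z**2), atol=1e-10
        )

    def test_variant_order_mismatch_rejected(self, rng):
        X = rng.standard_normal((100, 4))
        ref = make_ld_reference(X, list("abcd"), [0] * 4)
        pair = HarmonizedPair(
            variant_ids=list("abce"), z_g=np.zeros(4), z_i=np.zeros(4),
            n_g=10.0, n_i=10.0,
        )
        with pytest.raises(ValueError, match="ordering"):
            build_moment_table(pair, ref.eigenblocks)


class TestBaseline:
    def test_identity_ld_scores_degenerate(self, rng):
        z = rng.standard_normal(50)
        with pytest.raises(ValueError, match="degenerate"):
            baseline_ldsc_rho_ig(z, z, np.ones(50), N_G, N_I, M)

    def test_noise_free_products_recovered(self, rng):
        ell = rng.uniform(1.0, 8.0, 500)
        rho = 0.04
        y = np.sqrt(N_G * N_I) * rho * ell / M + 0.3
        # feed products via z_g = y, z_i = 1 so z_g*z_i = y
        slope_rho, intercept = baseline_ldsc_rho_ig(
            y, np.ones(500), ell, N_G, N_I, M, h2g=0.0, h2i=0.0, sigma1sq=0.0
        )
        np.testing.assert_allclose(slope_rho, rho, atol=1e-8)
        np.testing.assert_allclose(intercept, 0.3, atol=1e-6)


def test_estimate_all_reports_raw_and_derived(small_cfg, small_panel):
    from gxelder import simulate_study

    sim = simulate_study(small_cfg, 9, panel=small_panel)
    mt = build_moment_table(sim.to_pair(), small_panel.reference.eigenblocks)
    est = estimate_all(mt)
    d = est.as_dict()
    assert np.isfinite([d["h2g"], d["h2i"], d["rho_ig"], d["sigma1sq"]]).all()
    if est.h2g > 0 and est.h2i > 0:
        np.testing.assert_allclose(
            est.r_ig, est.rho_ig / np.sqrt(est.h2g * est.h2i)
        )
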