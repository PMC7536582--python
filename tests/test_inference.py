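"""Variational fit: conjugate oracles, ELBO behavior, SQUAREM, determinism."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from lemma_gxe import data_io, inference
from lemma_gxe.inference import (
    FitConfig,
    Hyperparameters,
    VariationalState,
    compute_elbo,
    coordinate_ascent_pass,
    environmental_score,
    fit,
    initialize_state,
    maximize_hyperparameters,
    squarem_step,
)

from conftest import bare_dataset, make_dataset


def gaussian_state(m, n, slab, spike, lam_b, lam_g, y):
    """Fresh state for a dataset with no covariates/environments."""
    return VariationalState(
        alpha_mean=np.zeros(0),
        alpha_var=np.zeros(0),
        w_mean=np.zeros(0),
        w_var=np.zeros(0),
        beta_resp=np.full(m, lam_b),
        beta_mean1=np.zeros(m),
        beta_var1=np.full(m, slab),
        beta_mean2=np.zeros(m),
        beta_var2=np.full(m, spike),
        gamma_resp=np.full(m, lam_g),
        gamma_mean1=np.zeros(m),
        gamma_var1=np.full(m, 1e-8),
        gamma_mean2=np.zeros(m),
        gamma_var2=np.full(m, 1e-8),
        r_lin=y.copy(),
        g=np.zeros(n),
        eta=np.zeros(n),
        eta2=np.zeros(n),
    )


def conjugate_phi(slab=0.5):
    # single-Gaussian limit: lambda ~ 1 and equal component variances
    return Hyperparameters(
        sigma_e2=1.0,
        sigma_b1=slab,
        sigma_b2=slab,
        sigma_g1=1e-8,
        sigma_g2=1e-8,
        lambda_b=1 - 1e-6,
        lambda_g=1e-6,
    )


class TestConjugateOracles:
    def test_single_snp_one_pass_matches_ridge_posterior(self, rng):
        n = 60
        x = data_io.standardize_columns(rng.standard_normal((n, 1)))[:, 0]
        y = 0.4 * x + rng.standard_normal(n)
        ds = bare_dataset(x[:, None], y)
        st = gaussian_state(1, n, 0.5, 0.5, 1 - 1e-6, 1e-6, y)
        st = coordinate_ascent_pass(st, conjugate_phi(), ds)
        expected = (x @ y) / (x @ x + 1.0 / 0.5)
        assert abs(st.beta_bar[0] - expected) < 1e-12

    def test_multi_snp_fixed_point_matches_ridge(self, rng):
        n, m = 100, 15
        X = data_io.standardize_columns(rng.standard_normal((n, m)))
        y = X @ (0.3 * rng.standard_normal(m)) + rng.standard_normal(n)
        ds = bare_dataset(X, y)
        st = gaussian_state(m, n, 0.5, 0.5, 1 - 1e-6, 1e-6, y)
        phi = conjugate_phi()
        prev = -np.inf
        for _ in range(600):
            st = coordinate_ascent_pass(st, phi, ds)
            e = compute_elbo(st, phi, ds)
            if abs(e - prev) < 1e-14:
                break
            prev = e
        ridge = np.linalg.solve(X.T @ X + np.eye(m) / 0.5, X.T @ y)
        np.testing.assert_allclose(st.beta_bar, ridge, atol=1e-6)

    def test_elbo_equals_log_marginal_at_exact_posterior(self, rng):
        # with one SNP the mean-field family contains the exact posterior
        n = 50
        x = data_io.standardize_columns(rng.standard_normal((n, 1)))[:, 0]
        y = 0.5 * x + rng.standard_normal(n)
        ds = bare_dataset(x[:, None], y)
        st = gaussian_state(1, n, 0.5, 0.5, 1 - 1e-6, 1e-6, y)
        phi = conjugate_phi()
        st = coordinate_ascent_pass(st, phi, ds)
        elbo = compute_elbo(st, phi, ds)
        log_marginal = multivariate_normal(
            mean=np.zeros(n), cov=np.eye(n) + 0.5 * np.outer(x, x)
        ).logpdf(y)
        assert abs(elbo - log_marginal) < 1e-8
        # any non-optimal q stays strictly below the marginal likelihood
        st.beta_mean1 += 0.3
        st.r_lin -= x * 0.3
        assert compute_elbo(st, phi, ds) < log_marginal - 1e-3

    def test_elbo_drops_when_residual_variance_inflated(self, small_sim):
        ds, _ = small_sim
        res = fit(ds, FitConfig(seed=0, max_passes=40))
        from dataclasses import replace

        worse = replace(res.phi, sigma_e2=res.phi.sigma_e2 * 1000)
        assert compute_elbo(res.state, worse, ds) < compute_elbo(res.state, res.phi, ds)


class TestCoordinateAscent:
    def test_cache_matches_recomputation(self, small_sim):
        ds, _ = small_sim
        state, phi = initialize_state(ds, FitConfig(seed=4))
        for _ in range(3):
            state = coordinate_ascent_pass(state, phi, ds)
        state.check_cache(ds, tol=1e-6)

    def test_no_signal_shrinks_posterior_means(self, rng):
        n, m = 200, 30
        X = data_io.standardize_columns(rng.standard_normal((n, m)))
        E = data_io.standardize_columns(rng.standard_normal((n, 3)))
        y = rng.standard_normal(n)  # independent of X and E
        ds = bare_dataset(X, y, E=E)
        state, phi = initialize_state(ds, FitConfig(seed=1))
        for _ in range(5):
            state = coordinate_ascent_pass(state, phi, ds)
        assert np.max(np.abs(state.beta_bar)) < 0.2
        assert np.mean(np.abs(state.beta_bar)) < 0.02

    def test_elbo_nondecreasing_within_passes(self, small_sim):
        ds, _ = small_sim
        state, phi = initialize_state(ds, FitConfig(seed=9))
        prev = -np.inf
        for _ in range(8):
            state = coordinate_ascent_pass(state, phi, ds)
            e = compute_elbo(state, phi, ds)
            assert e >= prev - 1e-8 * abs(prev)
            prev = e


class TestInitialization:
    def test_deterministic_per_seed(self, small_sim):
        ds, _ = small_sim
        s1, p1 = initialize_state(ds, FitConfig(seed=7))
        s2, p2 = initialize_state(ds, FitConfig(seed=7))
        np.testing.assert_array_equal(s1.w_mean, s2.w_mean)
        assert p1 == p2
        s3, _ = initialize_state(ds, FitConfig(seed=8))
        assert not np.allclose(s1.w_mean, s3.w_mean)

    def test_labeling_constraint_and_no_environment_error(self, small_sim):
        ds, _ = small_sim
        _, phi = initialize_state(ds, FitConfig(seed=0))
        assert phi.sigma_b1 >= phi.sigma_b2 and phi.sigma_g1 >= phi.sigma_g2
        import dataclasses

        bare = dataclasses.replace(ds, environments=np.empty((ds.n_samples, 0)))
        with pytest.raises(ValueError, match="environ"):
            initialize_state(bare, FitConfig(seed=0))


class TestMStep:
    def test_full_responsibility_clamps_lambda(self, small_sim):
        ds, _ = small_sim
        state, phi = initialize_state(ds, FitConfig(seed=2))
        state = coordinate_ascent_pass(state, phi, ds)
        state.beta_resp[:] = 1.0
        new = maximize_hyperparameters(state, ds, phi)
        assert new.lambda_b == pytest.approx(1 - 1e-6)
        assert new.sigma_a2 == phi.sigma_a2  # untouched

    def test_mstep_never_decreases_elbo(self):
        for seed in range(20):
            ds, _ = make_dataset(
                n_samples=120, n_snps=40, n_chrom=2, n_env=3, n_active_env=2,
                n_causal_main=8, n_causal_gxe=4, n_standardized_snps=0,
                var_std_main=0.0, var_std_gxe=0.0, seed=seed, env_seed=seed + 100,
            )
            state, phi = initialize_state(ds, FitConfig(seed=seed))
            state = coordinate_ascent_pass(state, phi, ds)
            before = compute_elbo(state, phi, ds)
            new_phi = maximize_hyperparameters(state, ds, phi)
            after = compute_elbo(state, new_phi, ds)
            assert after >= before - 1e-8 * abs(before)


class TestSquarem:
    def test_step_minus_one_returns_current_iterate(self, rng):
        p0, p1, p2 = rng.standard_normal((3, 7))
        np.testing.assert_allclose(squarem_step(p0, p1, p2, step=-1.0), p2, atol=1e-12)

    def test_hand_computed_scalar_sequence(self):
        # (0, 0.5, 0.75): d1 = 0.5, d2 = -0.25, v = min(-1, -0.25/0.0625) = -4
        # 0 - 2(-4)(0.5) + 16(-0.25) = 0
        assert squarem_step(0.0, 0.5, 0.75) == pytest.approx(0.0, abs=1e-12)

    def test_arithmetic_progression_returns_current(self):
        out = squarem_step(np.array([0.0]), np.array([1.0]), np.array([2.0]))
        np.testing.assert_allclose(out, [2.0])


class TestFit:
    def test_deterministic_trace(self, small_sim):
        ds, _ = small_sim
        r1 = fit(ds, FitConfig(seed=5, max_passes=30))
        r2 = fit(ds, FitConfig(seed=5, max_passes=30))
        assert r1.elbo_trace == r2.elbo_trace
        np.testing.assert_array_equal(r1.w_hat, r2.w_hat)

    def test_accepted_states_monotone(self, small_sim):
        ds, _ = small_sim
        res = fit(ds, FitConfig(seed=5, max_passes=60))
        tr = res.elbo_trace
        assert all(tr[i] >= tr[i - 1] - 1e-8 * abs(tr[i - 1]) for i in range(1, len(tr)))

    def test_recovers_environmental_score_direction(self):
        ds, truth = make_dataset(
            n_samples=1500, n_snps=600, n_chrom=4, n_env=5, n_active_env=1,
            n_causal_main=60, n_causal_gxe=60, n_standardized_snps=0,
            var_main=0.15, var_gxe=0.12, var_std_main=0.0, var_std_gxe=0.0,
            seed=31, env_seed=32,
        )
        res = fit(ds, FitConfig(seed=3, max_passes=100))
        r = abs(np.corrcoef(res.es, truth.eta)[0, 1])
        assert r > 0.6
        # the active environment carries the dominant weight
        active = int(np.flatnonzero(truth.w)[0])
        assert np.argmax(np.abs(res.w_hat)) == active

    def test_environment_rescaling_preserves_es_direction(self):
        # the N(0, I) prior on w pins the w/gamma scale split, so rescaling E
        # cannot change the fitted ES direction (only its arbitrary scale)
        ds, _ = make_dataset(
            n_samples=400, n_snps=100, n_chrom=2, n_env=4, n_active_env=2,
            n_causal_main=15, n_causal_gxe=10, n_standardized_snps=0,
            var_gxe=0.1, var_std_main=0.0, var_std_gxe=0.0, seed=41, env_seed=42,
        )
        import dataclasses

        base = fit(ds, FitConfig(seed=2, max_passes=80))
        for c in (0.5, 2.0):
            scaled = dataclasses.replace(ds, environments=ds.environments * c)
            res = fit(scaled, FitConfig(seed=2, max_passes=80))
            assert abs(np.corrcoef(res.es, base.es)[0, 1]) > 0.95

    def test_pure_noise_drifts_lambda_down(self, rng):
        n, m = 300, 80
        X = data_io.standardize_columns(rng.standard_normal((n, m)))
        E = data_io.standardize_columns(rng.standard_normal((n, 3)))
        y = rng.standard_normal(n)
        ds = bare_dataset(X, y, E=E, n_chrom=2)
        res = fit(ds, FitConfig(seed=1, max_passes=60))
        assert res.phi.lambda_b < 0.1 or res.phi.sigma_b1 < 1e-4

    def test_looser_tolerance_never_needs_more_passes(self, small_sim):
        ds, _ = small_sim
        tight = fit(ds, FitConfig(seed=6, elbo_tol=0.01, max_passes=80))
        loose = fit(ds, FitConfig(seed=6, elbo_tol=0.02, max_passes=80))
        assert loose.n_passes <= tight.n_passes

    def test_project_out_mode_removes_covariates(self, rng):
        n, m = 300, 60
        X = data_io.standardize_columns(rng.standard_normal((n, m)))
        E = data_io.standardize_columns(rng.standard_normal((n, 2)))
        C = np.column_stack([E, rng.standard_normal(n)])
        y = 2.0 * C[:, 2] + rng.standard_normal(n)
        ds = bare_dataset(X, y, E=E, C=C, n_chrom=2)
        res = fit(ds, FitConfig(seed=0, covariate_mode="project-out", max_passes=40))
        # covariate signal no longer reachable: residual phenotype orthogonal to C
        assert res.alpha_hat.size == 0
        assert res.converged


class TestEnvironmentalScore:
    def test_basic_identities(self, rng):
        E = data_io.standardize_columns(rng.standard_normal((40, 3)))
        np.testing.assert_array_equal(environmental_score(E, np.zeros(3)), np.zeros(40))
        np.testing.assert_array_equal(
            environmental_score(E[:, :1], np.array([1.0])), E[:, 0]
        )
        with pytest.raises(ValueError, match="columns"):
            environmental_score(E, np.ones(2))

    def test_norm_identity_for_orthogonal_standardized_columns(self, rng):
        n = 64
        q, _ = np.linalg.qr(rng.standard_normal((n, 4)))
        E = q * np.sqrt(n - 1)  # orthogonal columns with unit sample variance
        w = rng.standard_normal(4)
        eta = environmental_score(E, w)
        assert eta @ eta == pytest.approx((w @ w) * (n - 1), rel=1e-10)
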