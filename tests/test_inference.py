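"""Likelihood, priors, initialization, and sampler correctness."""

import numpy as np
import pytest
from scipy import integrate, stats

from dsemicro.inference import (
    MCMCSettings,
    PriorSet,
    VoxelPosterior,
    initialize_params,
    log_jacobian,
    log_prior,
    make_chain_state,
    ols_tensor_fit,
    rician_loglik,
    run_chain,
    summarize,
    to_natural,
    to_transformed,
    tune_proposals,
)
from dsemicro.signal_model import ProtocolCache, TissueParams


class TestRicianLoglik:
    def test_rayleigh_limit_at_zero_prediction(self):
        x, sigma = 0.7, 0.3
        expected = np.log(x / sigma**2) - x**2 / (2 * sigma**2)
        assert rician_loglik(x, 0.0, sigma) == pytest.approx(expected, rel=1e-12)

    def test_density_normalized(self):
        S, sigma = 1.0, 0.2
        total, _ = integrate.quad(
            lambda x: np.exp(rician_loglik(x, S, sigma)), 0, 10, limit=200
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_matches_scipy_rice(self):
        x = np.linspace(0.05, 3.0, 25)
        S, sigma = 0.8, 0.25
        ours = rician_loglik(x, S, sigma)
        ref = stats.rice.logpdf(x, b=S / sigma, scale=sigma)
        np.testing.assert_allclose(ours, ref, rtol=1e-9)

    def test_gaussian_limit_high_snr(self):
        x = S = 20.0
        sigma = 1.0
        gauss = -0.5 * np.log(2 * np.pi * sigma**2)
        assert abs(rician_loglik(x, S, sigma) - gauss) < 0.01

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            rician_loglik(1.0, 1.0, 0.0)


class TestLogPrior:
    def test_matches_scipy_componentwise(self):
        priors = PriorSet()
        p = TissueParams(f_i=0.2, f_r=0.5, D_par=1.5e-9, D_perp=0.9e-9, R=4e-6)
        expected = (
            stats.beta.logpdf(0.2, 1.2, 1.2)
            + stats.beta.logpdf(0.5 / 0.8, 5, 5)
            + stats.lognorm.logpdf(1.5e-9, 1.0, scale=np.exp(-20.69))
            + stats.lognorm.logpdf(0.9e-9, 1.0, scale=np.exp(-21.04))
            + stats.gamma.logpdf(4e-6, 3.562, scale=1.404e-6)
        )
        assert log_prior(p, 0.05, priors) == pytest.approx(expected, rel=1e-10)

    def test_gamma_prior_mode(self):
        # mode of Gamma(shape, scale) = (shape - 1) * scale ~ 3.60 um
        shape, scale = PriorSet().R_gamma
        mode = (shape - 1) * scale
        assert mode == pytest.approx(3.60e-6, abs=0.01e-6)
        grid = np.linspace(1e-6, 8e-6, 2001)
        dens = stats.gamma.pdf(grid, shape, scale=scale)
        assert grid[np.argmax(dens)] == pytest.approx(mode, abs=5e-9)

    def test_prior_means_match_stated_values(self):
        priors = PriorSet()
        assert priors.R_mean == pytest.approx(5e-6, abs=0.01e-6)
        assert priors.D_par_mean == pytest.approx(1.7e-9, rel=0.01)
        assert priors.D_perp_mean == pytest.approx(1.2e-9, rel=0.01)

    def test_beta_symmetry(self):
        priors = PriorSet()
        p1 = TissueParams(f_i=0.3, f_r=0.3)
        p2 = TissueParams(f_i=0.7, f_r=0.3 * (0.3 / 0.7))
        # only compare the f_i term: disable everything else
        only_fi = PriorSet(enabled=frozenset({"f_i"}))
        assert log_prior(p1, 0.05, only_fi) == pytest.approx(
            log_prior(p2, 0.05, only_fi)
        )

    def test_disabling_changes_only_that_term(self):
        p = TissueParams(f_i=0.1, f_r=0.6, R=4e-6)
        full = log_prior(p, 0.05, PriorSet())
        no_r = log_prior(p, 0.05, PriorSet().disable("R"))
        r_term = stats.gamma.logpdf(4e-6, 3.562, scale=1.404e-6)
        assert full - no_r == pytest.approx(r_term, rel=1e-9)

    def test_out_of_support_is_minus_inf(self):
        p = TissueParams(f_i=0.0, f_r=0.7)
        assert log_prior(p, 0.05, PriorSet()) == -np.inf  # f_i = 0 outside Beta support


class TestTensorFit:
    def _simulate_tensor_signals(self, protocol, tensor, s0=1.0):
        b = protocol.measurement_bvalues() * 1e6
        out = np.empty(protocol.n_measurements)
        for k, (i, d) in enumerate(protocol.measurement_table()):
            if d is None:
                out[k] = s0
            else:
                out[k] = s0 * np.exp(-b[k] * d @ tensor @ d)
        return out

    def test_isotropic_exact_recovery(self, protocol6):
        D = 1.1e-9
        sig = self._simulate_tensor_signals(protocol6, D * np.eye(3))
        evals, fa, _, log_s0, _ = ols_tensor_fit(sig, protocol6)
        np.testing.assert_allclose(evals, D, rtol=1e-6)
        assert fa == pytest.approx(0.0, abs=1e-6)
        assert log_s0 == pytest.approx(0.0, abs=1e-9)

    def test_prolate_recovery(self, protocol6):
        lam = np.diag([1.7e-9, 0.5e-9, 0.3e-9])
        rot = stats.special_ortho_group.rvs(3, random_state=1)
        tensor = rot @ lam @ rot.T
        sig = self._simulate_tensor_signals(protocol6, tensor)
        evals, fa, principal, _, _ = ols_tensor_fit(sig, protocol6)
        np.testing.assert_allclose(evals, np.diag(lam), rtol=1e-6)
        assert abs(principal @ rot[:, 0]) == pytest.approx(1.0, abs=1e-6)

    def test_too_few_measurements(self, protocol6):
        sig = np.zeros(protocol6.n_measurements)
        sig[:5] = 1.0
        with pytest.raises(ValueError):
            ols_tensor_fit(sig, protocol6)


class TestInitialization:
    def test_eq_structure(self):
        evals = np.array([1.7e-9, 0.5e-9, 0.3e-9])
        p = initialize_params(evals, np.array([0, 0, 1.0]), 0.0)
        assert p.D_par == pytest.approx(1.7e-9)
        assert p.D_perp == pytest.approx(0.4e-9)
        assert p.R == 5e-6
        f_i = 0.3e-9**2 / (1.7e-9 * 0.5e-9)
        assert p.f_i == pytest.approx(f_i)
        assert p.f_r == pytest.approx(0.7 * (1 - f_i))

    def test_f_i_clipped(self):
        evals = np.array([1e-9, 1e-9, 1e-9])  # ratio = 1 -> clipped below 1
        p = initialize_params(evals, np.array([0, 0, 1.0]), 0.0)
        assert 1e-3 <= p.f_i <= 1 - 1e-3

    def test_negative_eigenvalues_clamped(self):
        evals = np.array([1.7e-9, 0.5e-9, -1e-10])
        p = initialize_params(evals, np.array([1.0, 0, 0]), 0.0)
        assert p.D_perp > 0
        assert p.R == 5e-6


class TestTransforms:
    def test_roundtrip(self):
        p = TissueParams(S0=1.3, f_i=0.15, f_r=0.55, D_par=1.6e-9,
                         D_perp=0.8e-9, R=4.2e-6, theta=0.9, phi=2.1)
        x = to_transformed(p, 0.07)
        q, sigma = to_natural(x)
        assert sigma == pytest.approx(0.07)
        for attr in ("S0", "f_i", "f_r", "D_par", "D_perp", "R", "theta", "phi"):
            assert getattr(q, attr) == pytest.approx(getattr(p, attr), rel=1e-9)

    def test_acceptance_identical_natural_vs_transformed(self, protocol6):
        """MH accept/reject decisions agree whether the ratio is assembled in
        transformed space (posterior with Jacobian) or factor-by-factor in
        natural space, on a fixed random stream."""
        rng = np.random.default_rng(5)
        cache = ProtocolCache(protocol6)
        truth = TissueParams(f_i=0.05, f_r=0.65, theta=0.5, phi=1.0)
        data = cache.predict(truth) + rng.normal(0, 0.02, protocol6.n_measurements)
        data = np.abs(data)
        priors = PriorSet()
        post = VoxelPosterior(data, cache, priors)
        x = to_transformed(truth, 0.02)
        stream = np.random.default_rng(11)
        for _ in range(60):
            prop = x + stream.normal(0, 0.05, len(x))
            u = stream.uniform()
            ratio_t = post(prop) - post(x)
            # natural-space assembly
            def natural_logpost(xv):
                params, sigma = to_natural(xv)
                ll = float(np.sum(rician_loglik(data, cache.predict(params), sigma)))
                return ll + log_prior(params, sigma, priors) + log_jacobian(
                    xv, priors.enabled
                )

            ratio_n = natural_logpost(prop) - natural_logpost(x)
            assert (np.log(u) < ratio_t) == (np.log(u) < ratio_n)
            assert ratio_t == pytest.approx(ratio_n, rel=1e-9, abs=1e-9)
            if np.log(u) < ratio_t:
                x = prop


def _batch_se(x, n_batches=25):
    """Batch-means standard error of the mean for a correlated chain."""
    n = len(x) // n_batches * n_batches
    means = np.asarray(x[:n]).reshape(n_batches, -1).mean(axis=1)
    return means.std(ddof=1) / np.sqrt(n_batches)


class TestSampler:
    def test_tuning_reaches_band_on_toy_target(self):
        cov_diag = np.array([1.0, 0.04, 4.0, 0.25, 1.0, 9.0, 0.01, 1.0, 0.5])

        def logpost(x):
            return -0.5 * np.sum(x**2 / cov_diag)

        state = make_chain_state(np.zeros(9), fix={})
        settings = MCMCSettings(tune_epoch=400, max_tune_epochs=40)
        rng = np.random.default_rng(3)
        state, flagged = tune_proposals(state, logpost, settings, rng)
        assert not flagged
        rates = state.acceptance_rates
        assert np.all(rates >= 0.15) and np.all(rates <= 0.35)

    def test_prior_recovery_constant_likelihood(self, protocol6):
        """With the likelihood disabled the sampler must reproduce each
        informative prior's mean and variance (detailed-balance smoke test).
        """
        priors = PriorSet()
        settings = MCMCSettings(
            burn_in=1500, n_samples=2500, thin=4, seed=42,
            fix={"S0": 1.0, "theta": 0.2, "phi": 0.3, "sigma": 0.05},
        )
        dummy = np.ones(protocol6.n_measurements)
        post = run_chain(
            dummy, protocol6, priors, settings,
            init=TissueParams(f_i=0.3, f_r=0.4), sigma_init=0.05,
            use_likelihood=False,
        )
        checks = {
            "f_i": stats.beta(1.2, 1.2),
            "D_par": stats.lognorm(1.0, scale=np.exp(-20.69)),
            "D_perp": stats.lognorm(1.0, scale=np.exp(-21.04)),
            "R": stats.gamma(3.562, scale=1.404e-6),
        }
        for name, dist in checks.items():
            draws = post.samples[name]
            se = _batch_se(draws)
            assert abs(draws.mean() - dist.mean()) < 3 * se, name
            se_var = _batch_se((draws - draws.mean()) ** 2)
            assert abs(draws.var() - dist.var()) < 3 * se_var, name
        # f_r / (1 - f_i) ~ Beta(5, 5)
        frp = post.samples["f_r"] / (1 - post.samples["f_i"])
        assert abs(frp.mean() - 0.5) < 3 * _batch_se(frp)

    def test_zero_iterations_returns_initialization(self, protocol6):
        init = TissueParams(f_i=0.1, f_r=0.5, theta=0.4, phi=0.8)
        settings = MCMCSettings(burn_in=0, n_samples=1, thin=0, max_tune_epochs=0, seed=0)
        cache = ProtocolCache(protocol6)
        data = cache.predict(init)
        post = run_chain(data, protocol6, PriorSet(), settings, init=init, sigma_init=0.05)
        assert post.samples["R"][0] == pytest.approx(init.R, rel=1e-12)
        assert post.samples["f_r"][0] == pytest.approx(init.f_r, rel=1e-9)

    def test_high_snr_radius_recovery(self, protocol90):
        """Posterior median of R within 15% of the generative 5 um when the
        data are generated from the model itself at SNR 200."""
        cache = ProtocolCache(protocol90)
        truth = TissueParams(S0=1.0, f_i=0.0, f_r=0.7, D_par=1.7e-9,
                             D_perp=0.55e-9, R=5e-6, theta=1.1, phi=0.4)
        clean = cache.predict(truth)
        rng = np.random.default_rng(3)
        sd = 1 / 200
        noisy = np.sqrt(
            (clean + rng.normal(0, sd, clean.shape)) ** 2
            + rng.normal(0, sd, clean.shape) ** 2
        )
        settings = MCMCSettings(burn_in=2000, n_samples=50, thin=20, seed=7,
                                fix={"f_i": 0.0})
        post = run_chain(noisy, protocol90, PriorSet(), settings, cache=cache)
        summ = summarize(post)
        assert summ["radius_index"] == pytest.approx(5e-6, rel=0.15)

    def test_chain_consistency_across_seeds(self, protocol90):
        cache = ProtocolCache(protocol90)
        truth = TissueParams(f_i=0.0, f_r=0.7, D_par=1.7e-9, D_perp=0.55e-9,
                             R=5e-6, theta=1.1, phi=0.4)
        clean = cache.predict(truth)
        rng = np.random.default_rng(8)
        sd = 1 / 100
        noisy = np.sqrt(
            (clean + rng.normal(0, sd, clean.shape)) ** 2
            + rng.normal(0, sd, clean.shape) ** 2
        )
        medians = []
        for seed in (101, 202):
            settings = MCMCSettings(burn_in=2000, n_samples=50, thin=20,
                                    seed=seed, fix={"f_i": 0.0})
            post = run_chain(noisy, protocol90, PriorSet(), settings, cache=cache)
            medians.append(np.median(post.samples["R"]))
        # same data, different chains: medians agree within sampling error
        assert abs(medians[0] - medians[1]) / np.mean(medians) < 0.25

    def test_summarize_median_properties(self):
        from dsemicro.inference import PosteriorSamples

        samples = {k: np.full(5, 2.0) for k in
                   ("S0", "f_i", "f_r", "D_par", "D_perp", "R", "theta", "phi", "sigma")}
        post = PosteriorSamples(samples=samples, acceptance_rates=np.array([0.2]),
                                block_names=[["R"]], settings=MCMCSettings())
        s = summarize(post)
        assert s["R_median"] == 2.0
        assert s["radius_index"] == 2.0
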