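"""Oracles for the variational objective: Monte-Carlo moment and divergence
estimates, a brute-force reconstruction loop, and algebraic properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vaefusion.errors import ContractError
from vaefusion.nn import Tensor
from vaefusion.vae_core import (LatentDistribution, beta_vae_loss,
                                kl_standard_normal, kl_term_t, recon_term_t,
                                reconstruction_loss, reparameterize,
                                reparameterize_t)


def mc_kl_estimate(dist, n_samples, seed):
    """Monte-Carlo estimate of E_q[log q(z) - log p(z)] with its SE."""
    rng = np.random.default_rng(seed)
    sigma = np.exp(0.5 * dist.logvar)
    z = dist.mu + sigma * rng.standard_normal((n_samples, dist.dim))
    log_q = (-0.5 * ((z - dist.mu) / sigma) ** 2
             - 0.5 * np.log(2 * np.pi) - 0.5 * dist.logvar).sum(axis=1)
    log_p = (-0.5 * z ** 2 - 0.5 * np.log(2 * np.pi)).sum(axis=1)
    diff = log_q - log_p
    return diff.mean(), diff.std(ddof=1) / np.sqrt(n_samples)


class TestReparameterize:
    def test_zero_noise_returns_mean(self):
        dist = LatentDistribution(mu=np.array([3.0, -2.0]), logvar=np.array([1.0, 2.0]))
        np.testing.assert_array_equal(reparameterize(dist, np.zeros(2)).z, dist.mu)

    def test_unit_sigma_identity(self):
        dist = LatentDistribution(mu=np.array([1.0, 2.0]), logvar=np.zeros(2))
        np.testing.assert_array_equal(
            reparameterize(dist, np.array([1.0, -1.0])).z, [2.0, 1.0])

    def test_dim_mismatch_rejected(self):
        dist = LatentDistribution(mu=np.zeros(3), logvar=np.zeros(3))
        with pytest.raises(ContractError):
            reparameterize(dist, np.zeros(2))

    def test_moments_match_mu_sigma(self):
        """1e5 draws: sample mean -> mu and sample var -> sigma^2 within 4 SE."""
        dist = LatentDistribution(mu=np.array([0.7, -1.3, 2.0]),
                                  logvar=np.array([0.4, -0.8, 0.0]))
        rng = np.random.default_rng(42)
        n = 100_000
        draws = np.stack([
            reparameterize(dist, rng.standard_normal(3)).z for _ in range(1000)])
        # vectorised draws for the remaining samples (same distribution)
        eps = rng.standard_normal((n - 1000, 3))
        draws = np.vstack([draws, dist.mu + dist.sigma * eps])
        var = dist.sigma ** 2
        se_mean = dist.sigma / np.sqrt(n)
        se_var = var * np.sqrt(2.0 / (n - 1))
        assert np.all(np.abs(draws.mean(axis=0) - dist.mu) < 4 * se_mean)
        assert np.all(np.abs(draws.var(axis=0, ddof=1) - var) < 4 * se_var)


class TestKl:
    def test_prior_equals_posterior_is_zero(self):
        assert kl_standard_normal(
            LatentDistribution(mu=np.zeros(4), logvar=np.zeros(4))) == 0.0

    def test_unit_shift_is_half(self):
        assert kl_standard_normal(
            LatentDistribution(mu=np.array([1.0]), logvar=np.array([0.0]))) == 0.5

    def test_matches_monte_carlo_divergence(self):
        dist = LatentDistribution(mu=np.array([0.5, -0.5]),
                                  logvar=np.log(np.array([0.25, 4.0])))
        estimate, se = mc_kl_estimate(dist, 1_000_000, seed=0)
        assert abs(kl_standard_normal(dist) - estimate) < 3 * se

    def test_non_finite_rejected(self):
        with pytest.raises(ContractError):
            LatentDistribution(mu=np.array([np.nan]), logvar=np.array([0.0]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=8),
           st.lists(st.floats(-4, 4), min_size=1, max_size=8))
    def test_nonnegative(self, mu, logvar):
        d = min(len(mu), len(logvar))
        value = kl_standard_normal(
            LatentDistribution(mu=np.array(mu[:d]), logvar=np.array(logvar[:d])))
        assert value >= -1e-12


class TestReconstructionLoss:
    def test_identity_is_zero(self, rng):
        x = rng.normal(size=(3, 5))
        assert reconstruction_loss(x, x) == 0.0

    def test_scalar_plugin(self):
        assert reconstruction_loss(np.array(0.0), np.array(1.0)) == 1.0

    def test_matches_naive_double_loop(self, rng):
        x = rng.normal(size=(4, 3, 6, 6))
        x_hat = rng.normal(size=(4, 3, 6, 6))
        total = 0.0
        for b in range(4):
            acc = 0.0
            for value, other in zip(x[b].reshape(-1), x_hat[b].reshape(-1)):
                acc += (value - other) ** 2
            total += acc
        assert reconstruction_loss(x, x_hat) == pytest.approx(total / 4, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ContractError):
            reconstruction_loss(np.zeros((2, 3)), np.zeros((3, 2)))


class TestBetaVaeLoss:
    def test_beta_zero_is_pure_reconstruction(self):
        assert beta_vae_loss(2.5, 7.0, 0.0).total == 2.5

    def test_arithmetic(self):
        out = beta_vae_loss(2.0, 3.0, 1.0)
        assert out.total == 5.0
        assert out.total == pytest.approx(out.recon + out.beta * out.kl, abs=1e-9)

    @pytest.mark.parametrize("beta", [0.001, 0.1, 1, 2, 5, 10, 100])
    def test_grid_accepted(self, beta):
        assert beta_vae_loss(1.0, 1.0, beta).beta == beta

    def test_negative_beta_rejected(self):
        with pytest.raises(ContractError):
            beta_vae_loss(1.0, 1.0, -0.5)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(0.01, 10.0), st.floats(0.01, 10.0),
           st.floats(0.0, 50.0), st.floats(0.1, 50.0))
    def test_total_increasing_in_beta(self, recon, kl, beta, delta):
        assert beta_vae_loss(recon, kl, beta + delta).total \
            > beta_vae_loss(recon, kl, beta).total


def test_graph_losses_agree_with_numpy_route(rng):
    """The autodiff-graph loss terms equal the plain-numpy definitions."""
    mu = rng.normal(size=(6, 4))
    logvar = rng.normal(size=(6, 4)) * 0.5
    x = rng.normal(size=(6, 10))
    x_hat = rng.normal(size=(6, 10))
    dist = LatentDistribution(mu=mu, logvar=logvar)
    assert kl_term_t(Tensor(mu), Tensor(logvar)).item() \
        == pytest.approx(kl_standard_normal(dist), rel=1e-12)
    assert recon_term_t(Tensor(x), Tensor(x_hat)).item() \
        == pytest.approx(reconstruction_loss(x, x_hat), rel=1e-12)
    eps = rng.standard_normal((6, 4))
    np.testing.assert_allclose(
        reparameterize_t(Tensor(mu), Tensor(logvar), eps).data,
        mu + np.exp(0.5 * logvar) * eps, rtol=1e-12)
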