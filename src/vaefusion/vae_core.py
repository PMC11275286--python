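"""Mathematical core of the variational autoencoder objective.

The encoder maps an input x to a diagonal Gaussian approximate posterior
q(z|x) = N(mu, diag(sigma^2)); a latent code is drawn with the
reparameterization trick z = mu + sigma * eps, eps ~ N(0, I). Training
minimises a reconstruction term plus the KL divergence of the posterior from
the standard-normal prior, the latter weighted by a disentanglement factor
beta >= 0:

    L = L_rec + beta * KL[q(z|x) || N(0, I)]

beta = 1 recovers the plain VAE objective; larger beta trades reconstruction
fidelity for a posterior closer to the prior (more disentangled latents).

Two parallel surfaces are provided: plain-numpy functions operating on
:class:`LatentDistribution` (used for evaluation, logging and tests) and
graph functions suffixed ``_t`` operating on autodiff tensors (used inside
training loops). A test asserts the two routes agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .nn import Tensor

__all__ = ["LatentDistribution", "LatentCode", "LossBreakdown",
           "reparameterize", "kl_standard_normal", "reconstruction_loss",
           "beta_vae_loss", "reparameterize_t", "kl_term_t", "recon_term_t"]


@dataclass(frozen=True)
class LatentDistribution:
    """Diagonal Gaussian posterior parameters (mu, log sigma^2) per sample.

    Arrays may be 1-D (a single sample, d dims) or 2-D (batch, d).
    """

    mu: np.ndarray
    logvar: np.ndarray

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=np.float64)
        logvar = np.asarray(self.logvar, dtype=np.float64)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "logvar", logvar)
        if mu.shape != logvar.shape:
            raise ContractError(f"mu shape {mu.shape} != logvar shape {logvar.shape}")
        if mu.shape[-1] == 0:
            raise ContractError("latent dimension must be positive")
        if not (np.isfinite(mu).all() and np.isfinite(logvar).all()):
            raise ContractError("non-finite posterior parameters")

    @property
    def dim(self) -> int:
        return self.mu.shape[-1]

    @property
    def sigma(self) -> np.ndarray:
        return np.exp(0.5 * self.logvar)


@dataclass(frozen=True)
class LatentCode:
    z: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "z", np.asarray(self.z, dtype=np.float64))

    @property
    def dim(self) -> int:
        return self.z.shape[-1]


@dataclass(frozen=True)
class LossBreakdown:
    """One objective evaluation: recon + beta * kl = total."""

    recon: float
    kl: float
    beta: float
    total: float


def reparameterize(dist: LatentDistribution, epsilon: np.ndarray) -> LatentCode:
    """Draw z = mu + sigma * eps elementwise (the reparameterization trick)."""
    epsilon = np.asarray(epsilon, dtype=np.float64)
    if epsilon.shape != dist.mu.shape:
        raise ContractError(
            f"epsilon shape {epsilon.shape} does not match posterior shape {dist.mu.shape}")
    return LatentCode(dist.mu + dist.sigma * epsilon)


def kl_standard_normal(dist: LatentDistribution) -> float:
    """Closed-form KL[N(mu, diag(sigma^2)) || N(0, I)].

    0.5 * sum_i (mu_i^2 + sigma_i^2 - 1 - log sigma_i^2), summed over latent
    dims; for a batched distribution the per-sample KLs are averaged.
    """
    per_dim = 0.5 * (dist.mu ** 2 + np.exp(dist.logvar) - 1.0 - dist.logvar)
    per_sample = per_dim.sum(axis=-1)
    return float(np.mean(per_sample))


def reconstruction_loss(x: np.ndarray, x_hat: np.ndarray, kind: str = "mse") -> float:
    """Squared-error reconstruction loss: summed over feature dims, averaged
    over the batch (leading axis; a single sample counts as a batch of one)."""
    if kind != "mse":
        raise ContractError(f"unknown reconstruction loss kind: {kind!r}")
    x = np.asarray(x, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    if x.shape != x_hat.shape:
        raise ContractError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    sq = (x - x_hat) ** 2
    if sq.ndim == 0:
        return float(sq)
    per_sample = sq.reshape(sq.shape[0], -1).sum(axis=1)
    return float(per_sample.mean())


def beta_vae_loss(recon: float, kl: float, beta: float) -> LossBreakdown:
    """Combine the two loss terms into the beta-weighted objective."""
    if beta < 0:
        raise ContractError(f"beta must be >= 0, got {beta}")
    return LossBreakdown(recon=float(recon), kl=float(kl), beta=float(beta),
                         total=float(recon) + float(beta) * float(kl))


# -- autodiff-graph counterparts (used by the training loops) -----------------

def reparameterize_t(mu: Tensor, logvar: Tensor, epsilon: np.ndarray) -> Tensor:
    return mu + (logvar * 0.5).exp() * Tensor(epsilon)


def kl_term_t(mu: Tensor, logvar: Tensor) -> Tensor:
    """Graph version of the closed-form KL: mean over batch, sum over dims."""
    per_dim = (mu ** 2.0 + logvar.exp() - 1.0 - logvar) * 0.5
    return per_dim.sum(axis=-1).mean()


def recon_term_t(x: Tensor, x_hat: Tensor) -> Tensor:
    """Graph version of the reconstruction loss (sum-over-features, batch mean)."""
    n = x.shape[0]
    sq = (x - x_hat) ** 2.0
    return sq.reshape(n, -1).sum(axis=1).mean()
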