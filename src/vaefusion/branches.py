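"""The two generative branches and the pluggable feature backbone.

* An image-space convolutional VAE: three stride-2 convolutions (32-32-64
  channels, 3x3 kernels), each followed by batch normalization and a
  leaky-rectifier, then a fully connected trunk (128-128-128-64-64-32-32)
  feeding two parallel linear heads that emit the posterior mean and
  log-variance of a 32-dimensional latent. The decoder mirrors the encoder
  with transposed convolutions.
* A feature-space beta-VAE: a fully connected encoder/decoder over
  1024-dimensional backbone features, trained with the KL term weighted by
  beta.

One branch instance is trained per radiograph view (frontal, lateral); their
parameters are disjoint. The backbone is pluggable: the default
``toy_deterministic`` backbone is a fixed-seed random convolutional feature
extractor with spatial average pooling and a random projection to the
configured dimension — deterministic, download-free, and adequate as a
generic feature map. A DenseNet-style pretrained backbone can be plugged in
through the same interface where its weights are available.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, ContractError
from .imageprep import ImageTensor
from .nn import (Adam, BatchNorm, Conv2d, ConvTranspose2d, LeakyReLU, Linear,
                 Module, Sequential, Tensor)
from .vae_core import (LatentDistribution, LossBreakdown, beta_vae_loss,
                       kl_term_t, recon_term_t, reparameterize_t)

__all__ = ["ImageVaeConfig", "FeatureBetaVaeConfig", "BackboneSpec",
           "ImageVae", "FeatureBetaVae", "extract_features", "train_branch",
           "images_to_batch", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ImageVaeConfig:
    input_size: int = 224
    conv_channels: tuple[int, ...] = (32, 32, 64)
    kernel: int = 3
    stride: int = 2
    fc_stack: tuple[int, ...] = (128, 128, 128, 64, 64, 32, 32)
    latent_dim: int = 32

    def __post_init__(self):
        if self.latent_dim <= 0:
            raise ConfigurationError("latent_dim must be positive")
        if self.input_size % (self.stride ** len(self.conv_channels)) != 0:
            raise ConfigurationError(
                f"input_size {self.input_size} is not divisible by "
                f"stride^{len(self.conv_channels)}")


@dataclass(frozen=True)
class FeatureBetaVaeConfig:
    input_dim: int = 1024
    hidden: tuple[int, ...] = (256, 256)
    latent_dim: int = 32
    beta: float = 0.001

    def __post_init__(self):
        if self.beta < 0:
            raise ConfigurationError("beta must be >= 0")
        if self.latent_dim <= 0 or self.input_dim <= 0:
            raise ConfigurationError("dimensions must be positive")


@dataclass(frozen=True)
class BackboneSpec:
    name: str = "toy-conv"
    output_dim: int = 1024
    weights_source: str = "toy_deterministic"  # or "pretrained"


def images_to_batch(images: list[ImageTensor] | np.ndarray) -> np.ndarray:
    """Stack images into an NCHW float batch."""
    if isinstance(images, np.ndarray):
        arr = images
        if arr.ndim == 3:
            arr = arr[None]
        if arr.shape[-1] == 3:
            arr = arr.transpose(0, 3, 1, 2)
        return np.ascontiguousarray(arr, dtype=np.float64)
    return images_to_batch(np.stack([im.pixels for im in images], axis=0))


# ---------------------------------------------------------------------------
# Backbone
# ---------------------------------------------------------------------------

class _ToyBackbone:
    """Fixed-seed random convolutional feature extractor.

    Two random strided convolutions with rectification, average pooling onto
    a 4x4 spatial grid, then a fixed random projection to `output_dim`. The
    weights are a pure function of (name, output_dim), so features are
    bitwise-stable across processes and runs.
    """

    _POOL_GRID = 4

    def __init__(self, spec: BackboneSpec):
        seed = zlib.crc32(f"{spec.name}:{spec.output_dim}".encode()) % (2 ** 31)
        rng = np.random.default_rng(seed)
        self.w1 = rng.normal(0, np.sqrt(2.0 / (3 * 25)), size=(16, 3 * 5 * 5))
        self.w2 = rng.normal(0, np.sqrt(2.0 / (16 * 9)), size=(32, 16 * 3 * 3))
        g = self._POOL_GRID
        self.proj = rng.normal(0, np.sqrt(1.0 / (32 * g * g)),
                               size=(32 * g * g, spec.output_dim))

    @staticmethod
    def _conv(x: np.ndarray, w: np.ndarray, k: int, stride: int) -> np.ndarray:
        from .nn.autograd import _im2col_raw
        n, _, h, _ = x.shape
        oh = (h + 2 - k) // stride + 1
        cols = _im2col_raw(x, k, stride, 1)
        return (w @ cols).reshape(n, w.shape[0], oh, oh)

    def __call__(self, batch: np.ndarray) -> np.ndarray:
        x = np.maximum(self._conv(batch, self.w1, 5, 4), 0.0)
        x = np.maximum(self._conv(x, self.w2, 3, 2), 0.0)
        n, c, h, w = x.shape
        g = self._POOL_GRID
        # adaptive average pooling onto a g x g grid; bins overlap when the
        # feature map is smaller than the grid, so every bin is non-empty
        def bins(extent):
            edges = [(int(np.floor(i * extent / g))) for i in range(g + 1)]
            return [np.arange(lo, max(lo + 1, hi))
                    for lo, hi in zip(edges[:-1], edges[1:])]

        pooled = np.empty((n, c, g, g))
        for i, hi in enumerate(bins(h)):
            for j, wj in enumerate(bins(w)):
                pooled[:, :, i, j] = x[:, :, hi][:, :, :, wj].mean(axis=(2, 3))
        return pooled.reshape(n, -1) @ self.proj


_BACKBONE_CACHE: dict[tuple[str, int], _ToyBackbone] = {}


def extract_features(images, spec: BackboneSpec) -> np.ndarray:
    """Map a batch of (normalized) images to per-image feature vectors."""
    if spec.weights_source == "pretrained":
        raise ConfigurationError(
            "pretrained backbone weights are not bundled; use "
            "weights_source='toy_deterministic' or supply a feature file")
    if spec.weights_source != "toy_deterministic":
        raise ConfigurationError(f"unknown weights_source {spec.weights_source!r}")
    key = (spec.name, spec.output_dim)
    if key not in _BACKBONE_CACHE:
        _BACKBONE_CACHE[key] = _ToyBackbone(spec)
    return _BACKBONE_CACHE[key](images_to_batch(images))


# ---------------------------------------------------------------------------
# Branch networks
# ---------------------------------------------------------------------------

class ImageVae(Module):
    """Convolutional VAE over radiograph pixels (encoder E2 / decoder D2)."""

    def __init__(self, config: ImageVaeConfig, rng: np.random.Generator):
        self.config = config
        c = config
        layers: list[Module] = []
        in_ch = 3
        for ch in c.conv_channels:
            layers += [Conv2d(in_ch, ch, c.kernel, c.stride, pad=1, rng=rng),
                       BatchNorm(ch), LeakyReLU()]
            in_ch = ch
        self.enc_conv = Sequential(*layers)
        self.final_hw = c.input_size // (c.stride ** len(c.conv_channels))
        self.flat_dim = c.conv_channels[-1] * self.final_hw ** 2
        trunk: list[Module] = []
        in_f = self.flat_dim
        for units in c.fc_stack:
            trunk += [Linear(in_f, units, rng), LeakyReLU()]
            in_f = units
        self.enc_fc = Sequential(*trunk)
        self.head_mu = Linear(in_f, c.latent_dim, rng)
        self.head_logvar = Linear(in_f, c.latent_dim, rng)

        dec: list[Module] = []
        in_f = c.latent_dim
        for units in reversed(c.fc_stack):
            dec += [Linear(in_f, units, rng), LeakyReLU()]
            in_f = units
        dec += [Linear(in_f, self.flat_dim, rng), LeakyReLU()]
        self.dec_fc = Sequential(*dec)
        dconv: list[Module] = []
        channels = list(reversed(c.conv_channels))
        for i, ch in enumerate(channels):
            out_ch = channels[i + 1] if i + 1 < len(channels) else 3
            dconv.append(ConvTranspose2d(ch, out_ch, c.kernel, c.stride,
                                         pad=1, output_pad=1, rng=rng))
            if i + 1 < len(channels):
                dconv += [BatchNorm(out_ch), LeakyReLU()]
        self.dec_conv = Sequential(*dconv)

    # graph-mode (training) -------------------------------------------------
    def encode_t(self, x: Tensor) -> tuple[Tensor, Tensor]:
        n = x.shape[0]
        h = self.enc_conv(x).reshape(n, self.flat_dim)
        h = self.enc_fc(h)
        return self.head_mu(h), self.head_logvar(h)

    def decode_t(self, z: Tensor) -> Tensor:
        n = z.shape[0]
        h = self.dec_fc(z)
        ch = self.config.conv_channels[-1]
        return self.dec_conv(h.reshape(n, ch, self.final_hw, self.final_hw))

    # inference -------------------------------------------------------------
    def encode(self, images) -> LatentDistribution:
        batch = images_to_batch(images) if not isinstance(images, Tensor) else images.data
        if batch.shape[-1] != self.config.input_size:
            raise ConfigurationError(
                f"input size {batch.shape[-2:]} does not match configured "
                f"{self.config.input_size}")
        self.eval()
        mu, logvar = self.encode_t(Tensor(batch))
        self.train()
        return LatentDistribution(mu=mu.data, logvar=logvar.data)

    def decode(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        if z.shape[-1] != self.config.latent_dim:
            raise ContractError(f"latent dim {z.shape[-1]} != {self.config.latent_dim}")
        self.eval()
        out = self.decode_t(Tensor(z)).data
        self.train()
        return out


class FeatureBetaVae(Module):
    """Fully connected beta-VAE over backbone features (E1 / D1)."""

    def __init__(self, config: FeatureBetaVaeConfig, rng: np.random.Generator):
        self.config = config
        enc: list[Module] = []
        in_f = config.input_dim
        for units in config.hidden:
            enc += [Linear(in_f, units, rng), LeakyReLU()]
            in_f = units
        self.enc = Sequential(*enc)
        self.head_mu = Linear(in_f, config.latent_dim, rng)
        self.head_logvar = Linear(in_f, config.latent_dim, rng)
        dec: list[Module] = []
        in_f = config.latent_dim
        for units in reversed(config.hidden):
            dec += [Linear(in_f, units, rng), LeakyReLU()]
            in_f = units
        dec.append(Linear(in_f, config.input_dim, rng))
        self.dec = Sequential(*dec)

    def encode_t(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = self.enc(x)
        return self.head_mu(h), self.head_logvar(h)

    def decode_t(self, z: Tensor) -> Tensor:
        return self.dec(z)

    def encode(self, features: np.ndarray) -> LatentDistribution:
        features = np.atleast_2d(np.asarray(features, dtype=np.float64))
        if features.shape[-1] != self.config.input_dim:
            raise ContractError(
                f"feature dim {features.shape[-1]} != {self.config.input_dim}")
        mu, logvar = self.encode_t(Tensor(features))
        return LatentDistribution(mu=mu.data, logvar=logvar.data)

    def decode(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        if z.shape[-1] != self.config.latent_dim:
            raise ContractError(f"latent dim {z.shape[-1]} != {self.config.latent_dim}")
        return self.decode_t(Tensor(z)).data


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train_branch(branch: Module, dataset: np.ndarray, epochs: int,
                 batch_size: int, optimizer_config: dict | None = None,
                 seed: int = 0, beta: float = 1.0) -> list[LossBreakdown]:
    """Train one branch by minimising recon + beta * KL with Adam.

    `dataset` is the full training array for that branch and view: NCHW (or
    NHWC) images for the image VAE, (n, input_dim) features for the feature
    beta-VAE. Returns the per-epoch loss history; `epochs=0` leaves the
    branch at initialisation with an empty history. A non-finite loss aborts
    with the epoch and batch index in the message.
    """
    if dataset.shape[0] == 0:
        raise ContractError("empty training dataset")
    if isinstance(branch, ImageVae):
        data = images_to_batch(dataset)
    else:
        data = np.atleast_2d(np.asarray(dataset, dtype=np.float64))
    optimizer_config = dict(optimizer_config or {})
    opt = Adam(branch.parameters(), lr=optimizer_config.get("lr", 1e-3))
    rng = np.random.default_rng(seed)
    n = data.shape[0]
    history: list[LossBreakdown] = []
    branch.train()
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_recon, epoch_kl, n_batches = 0.0, 0.0, 0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            x = Tensor(data[idx])
            mu, logvar = branch.encode_t(x)
            eps = rng.standard_normal(mu.shape)
            z = reparameterize_t(mu, logvar, eps)
            x_hat = branch.decode_t(z)
            recon = recon_term_t(x, x_hat)
            kl = kl_term_t(mu, logvar)
            total = recon + kl * beta
            if not np.isfinite(total.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}")
            opt.zero_grad()
            total.backward()
            opt.step()
            epoch_recon += recon.item()
            epoch_kl += kl.item()
            n_batches += 1
        history.append(beta_vae_loss(epoch_recon / n_batches,
                                     epoch_kl / n_batches, beta))
    return history


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(branch: Module, path: str | Path, seed: int | None = None,
                    extra: dict | None = None) -> None:
    """Serialise a branch (weights + config + seed) to a single .npz file."""
    meta = {"kind": type(branch).__name__,
            "config": asdict(branch.config),
            "seed": seed, **(extra or {})}
    state = branch.state()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path: str | Path) -> Module:
    with np.load(path) as payload:
        meta = json.loads(bytes(payload["__meta__"]).decode())
        state = {k: payload[k] for k in payload.files if k != "__meta__"}
    rng = np.random.default_rng(0)  # weights overwritten below
    if meta["kind"] == "ImageVae":
        cfg = meta["config"]
        for key in ("conv_channels", "fc_stack"):
            cfg[key] = tuple(cfg[key])
        branch: Module = ImageVae(ImageVaeConfig(**cfg), rng)
    elif meta["kind"] == "FeatureBetaVae":
        cfg = meta["config"]
        cfg["hidden"] = tuple(cfg["hidden"])
        branch = FeatureBetaVae(FeatureBetaVaeConfig(**cfg), rng)
    else:
        raise ConfigurationError(f"unknown checkpoint kind {meta['kind']!r}")
    branch.load_state(state)
    return branch
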