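"""Branch architectures, the deterministic toy backbone, branch training,
and checkpoint round-trips."""

import numpy as np
import pytest

from vaefusion.branches import (BackboneSpec, FeatureBetaVae,
                                FeatureBetaVaeConfig, ImageVae, ImageVaeConfig,
                                extract_features, load_checkpoint,
                                save_checkpoint, train_branch)
from vaefusion.errors import ConfigurationError, ContractError

DESK = ImageVaeConfig(input_size=32, conv_channels=(8, 8), fc_stack=(32, 16),
                      latent_dim=8)


class TestBackbone:
    def test_output_is_n_by_1024(self, rng):
        feats = extract_features(rng.normal(size=(4, 3, 32, 32)), BackboneSpec())
        assert feats.shape == (4, 1024)

    def test_identical_images_identical_rows(self, rng):
        img = rng.normal(size=(3, 32, 32))
        feats = extract_features(np.stack([img, img]), BackboneSpec())
        np.testing.assert_array_equal(feats[0], feats[1])

    def test_bitwise_stable_across_calls(self, rng):
        batch = rng.normal(size=(2, 3, 32, 32))
        a = extract_features(batch, BackboneSpec())
        b = extract_features(batch.copy(), BackboneSpec())
        np.testing.assert_array_equal(a, b)

    def test_pretrained_unavailable_suggests_toy(self, rng):
        spec = BackboneSpec(weights_source="pretrained")
        with pytest.raises(ConfigurationError, match="toy_deterministic"):
            extract_features(rng.normal(size=(1, 3, 32, 32)), spec)


class TestImageVae:
    def test_default_config_latents_are_32_dim(self, rng):
        vae = ImageVae(ImageVaeConfig(input_size=64), np.random.default_rng(0))
        dist = vae.encode(rng.normal(size=(2, 3, 64, 64)))
        assert dist.mu.shape == (2, 32) and dist.logvar.shape == (2, 32)

    def test_batching(self, rng):
        vae = ImageVae(DESK, np.random.default_rng(0))
        dist = vae.encode(rng.normal(size=(5, 3, 32, 32)))
        assert dist.mu.shape == (5, 8)

    def test_decode_shape_mirrors_input(self, rng):
        vae = ImageVae(DESK, np.random.default_rng(0))
        out = vae.decode(rng.normal(size=(3, 8)))
        assert out.shape == (3, 3, 32, 32)

    def test_decode_deterministic(self, rng):
        vae = ImageVae(DESK, np.random.default_rng(0))
        z = rng.normal(size=(2, 8))
        np.testing.assert_array_equal(vae.decode(z), vae.decode(z))

    def test_encode_decode_roundtrip_shape(self, rng):
        """decode(encode(x) sample) matches x's shape for any configured size."""
        for size in (16, 32):
            cfg = ImageVaeConfig(input_size=size, conv_channels=(4, 4),
                                 fc_stack=(16,), latent_dim=4)
            vae = ImageVae(cfg, np.random.default_rng(0))
            x = rng.normal(size=(2, 3, size, size))
            dist = vae.encode(x)
            eps = rng.standard_normal(dist.mu.shape)
            z = dist.mu + dist.sigma * eps
            assert vae.decode(z).shape == x.shape

    def test_input_size_mismatch_rejected(self, rng):
        vae = ImageVae(DESK, np.random.default_rng(0))
        with pytest.raises(ConfigurationError):
            vae.encode(rng.normal(size=(1, 3, 16, 16)))

    def test_latent_dim_mismatch_rejected(self, rng):
        vae = ImageVae(DESK, np.random.default_rng(0))
        with pytest.raises(ContractError):
            vae.decode(rng.normal(size=(1, 5)))


class TestFeatureBetaVae:
    def test_1024_features_to_32_dim_mu(self, rng):
        vae = FeatureBetaVae(FeatureBetaVaeConfig(), np.random.default_rng(0))
        dist = vae.encode(rng.normal(size=(3, 1024)))
        assert dist.mu.shape == (3, 32)

    def test_decode_restores_input_dim(self, rng):
        vae = FeatureBetaVae(FeatureBetaVaeConfig(), np.random.default_rng(0))
        dist = vae.encode(rng.normal(size=(2, 1024)))
        assert vae.decode(dist.mu).shape == (2, 1024)

    def test_overfit_small_set_reduces_recon_by_90pct(self, rng):
        cfg = FeatureBetaVaeConfig(input_dim=32, hidden=(64,), latent_dim=8)
        vae = FeatureBetaVae(cfg, np.random.default_rng(0))
        data = rng.normal(size=(8, 32))
        history = train_branch(vae, data, epochs=200, batch_size=8, seed=1,
                               beta=0.0)
        assert history[-1].recon < 0.1 * history[0].recon


class TestTrainBranch:
    def test_zero_epochs_is_noop_with_empty_history(self, rng):
        vae = FeatureBetaVae(FeatureBetaVaeConfig(input_dim=16, hidden=(8,),
                                                  latent_dim=4),
                             np.random.default_rng(0))
        before = {k: v.copy() for k, v in vae.state().items()}
        history = train_branch(vae, rng.normal(size=(4, 16)), epochs=0,
                               batch_size=4)
        assert history == []
        for key, value in vae.state().items():
            np.testing.assert_array_equal(value, before[key])

    def test_seeded_training_descends(self, rng):
        vae = ImageVae(DESK, np.random.default_rng(0))
        data = rng.normal(size=(8, 3, 32, 32)) * 0.2
        history = train_branch(vae, data, epochs=10, batch_size=8, seed=5,
                               beta=1.0)
        assert history[-1].total < history[0].total

    def test_image_vae_overfits_constant_images(self, rng):
        cfg = ImageVaeConfig(input_size=16, conv_channels=(4, 4),
                             fc_stack=(16,), latent_dim=4)
        vae = ImageVae(cfg, np.random.default_rng(0))
        data = np.full((6, 3, 16, 16), 0.3)
        history = train_branch(vae, data, epochs=300, batch_size=6, seed=2,
                               beta=0.0, optimizer_config={"lr": 5e-3})
        assert history[-1].recon < 0.1 * history[0].recon

    def test_empty_dataset_rejected(self):
        vae = FeatureBetaVae(FeatureBetaVaeConfig(input_dim=8, hidden=(8,),
                                                  latent_dim=2),
                             np.random.default_rng(0))
        with pytest.raises(ContractError):
            train_branch(vae, np.empty((0, 8)), epochs=1, batch_size=4)


def test_beta_pressure_trades_kl_for_reconstruction(rng):
    """Large beta drives the mean KL below a small-beta run while the
    reconstruction error ends up higher — the disentanglement trade-off."""
    data = rng.normal(size=(32, 16))
    results = {}
    for beta in (0.001, 100.0):
        cfg = FeatureBetaVaeConfig(input_dim=16, hidden=(32,), latent_dim=4)
        vae = FeatureBetaVae(cfg, np.random.default_rng(1))
        history = train_branch(vae, data, epochs=120, batch_size=32, seed=3,
                               beta=beta)
        results[beta] = history[-1]
    assert results[100.0].kl < results[0.001].kl
    assert results[100.0].recon > results[0.001].recon


def test_checkpoint_roundtrip_preserves_weights_and_config(tmp_path, rng):
    vae = ImageVae(DESK, np.random.default_rng(4))
    train_branch(vae, rng.normal(size=(4, 3, 32, 32)), epochs=2, batch_size=4,
                 seed=0)
    save_checkpoint(vae, tmp_path / "ck.npz", seed=0)
    loaded = load_checkpoint(tmp_path / "ck.npz")
    assert loaded.config == vae.config
    x = rng.normal(size=(2, 3, 32, 32))
    np.testing.assert_array_equal(loaded.encode(x).mu, vae.encode(x).mu)
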