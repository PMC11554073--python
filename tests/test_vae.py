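"""VAE construction, ELBO arithmetic, training behaviour, feature extraction."""

import numpy as np
import pytest

from kpsfusion.synthetic import TumorGeometry, simulate_tumor_volume
from kpsfusion.vae import (Vae, VaeConfig, assemble_mri_features, build_vae,
                           elbo_loss, extract_latent, load_checkpoint,
                           pretrain, save_checkpoint)
from kpsfusion.volumes import make_slice_stack

TOY = dict(input_shape=(24, 16, 16), pool=(2, 4, 4), hidden_widths=(32,))


def _stacks(n, seed, grid=(28, 16, 16), radius=3.0):
    """Small synthetic slice stacks for training tests."""
    rng = np.random.default_rng(seed)
    out = []
    centre = tuple((g - 1) / 2 for g in grid)
    for _ in range(n):
        r = radius * rng.uniform(0.8, 1.2)
        geom = TumorGeometry(center=tuple(g // 2 for g in grid),
                             core_radii=(r * 0.6, r, r), edema_margin=1.5,
                             brain_center=centre,
                             brain_radii=tuple(0.47 * g for g in grid))
        v = simulate_tumor_volume(geom, grid, seed=rng)
        out.append(make_slice_stack(v))
    return out


class TestElboLoss:
    def test_kl_zero_at_prior(self):
        _, _, kl = elbo_loss(np.zeros((1, 4)), np.zeros((1, 4)),
                             np.zeros((1, 48)), np.zeros((1, 48)))
        assert kl == 0.0

    def test_kl_unit_mean_single_dim(self):
        mu = np.zeros((1, 48))
        mu[0, 0] = 1.0
        _, _, kl = elbo_loss(np.zeros((1, 4)), np.zeros((1, 4)),
                             mu, np.zeros((1, 48)))
        assert kl == pytest.approx(0.5)  # sum over dims, mean over batch

    def test_saturated_reconstruction_vanishes(self):
        x = np.array([[0.0, 1.0, 1.0, 0.0]])
        logits = np.where(x > 0, 50.0, -50.0)
        _, rec, _ = elbo_loss(x, logits, np.zeros((1, 2)), np.zeros((1, 2)))
        assert rec == pytest.approx(0.0, abs=1e-12)

    def test_kl_nonnegative_random(self, rng):
        for _ in range(50):
            mu = rng.normal(size=(3, 8))
            lv = rng.normal(size=(3, 8))
            _, _, kl = elbo_loss(np.zeros((3, 2)), np.zeros((3, 2)), mu, lv)
            assert kl >= 0.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            elbo_loss(np.array([[np.nan]]), np.array([[0.0]]),
                      np.zeros((1, 1)), np.zeros((1, 1)))


class TestBuildVae:
    def test_latent_dimension_is_48(self):
        vae = build_vae(VaeConfig(input_channels=2, **TOY))
        x = np.zeros((3, 24, 16, 16, 2))
        mu, logvar = vae.encode(vae._pool_flatten(x))
        assert mu.shape == (3, 48) and logvar.shape == (3, 48)
        assert vae.n_params() > 0

    def test_toy_latent_roundtrips_shapes(self):
        vae = build_vae(VaeConfig(latent_dim=1, input_channels=1, **TOY))
        x = np.random.default_rng(0).random((2, 24, 16, 16, 1)) > 0.5
        logits = vae.reconstruct_logits(x.astype(float))
        assert logits.shape == (2, vae.config.flat_dim())

    def test_indivisible_shape_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            Vae(VaeConfig(input_shape=(24, 15, 16), pool=(2, 4, 4)))


class TestPretrain:
    def test_loss_decreases(self):
        stacks = _stacks(20, seed=0)
        vae = Vae(VaeConfig(input_channels=2, epochs=5, seed=1, **TOY))
        hist = pretrain(vae, stacks)
        assert len(hist) == 5
        assert hist[-1] < hist[0]

    def test_all_zero_stacks_trivially_learned(self):
        # one epoch of single-sample steps is enough to drive the logits down
        stacks = _stacks(64, seed=1)
        for s in stacks:
            s.lesion = np.zeros_like(s.lesion)
        vae = Vae(VaeConfig(input_channels=2, epochs=1, seed=2, batch_size=1,
                            learning_rate=0.2, **TOY))
        pretrain(vae, stacks)
        x = np.stack([s.lesion for s in stacks[:8]]).astype(float)
        _, rec, _ = elbo_loss(vae._pool_flatten(x),
                              vae.reconstruct_logits(x),
                              *vae.encode(vae._pool_flatten(x)))
        assert rec < 0.05

    def test_reproducible_histories(self):
        stacks = _stacks(10, seed=2)
        h1 = pretrain(Vae(VaeConfig(input_channels=2, epochs=3, seed=5, **TOY)), stacks)
        h2 = pretrain(Vae(VaeConfig(input_channels=2, epochs=3, seed=5, **TOY)), stacks)
        assert h1 == h2

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            pretrain(Vae(VaeConfig(**TOY)), [])

    def test_checkpoint_roundtrip_exact_latents(self, tmp_path):
        stacks = _stacks(6, seed=3)
        vae = Vae(VaeConfig(input_channels=2, epochs=2, seed=3, **TOY))
        pretrain(vae, stacks)
        save_checkpoint(vae, tmp_path / "vae.npz")
        back = load_checkpoint(tmp_path / "vae.npz")
        a = extract_latent(vae, stacks[0], "pre_lesion").mu
        b = extract_latent(back, stacks[0], "pre_lesion").mu
        np.testing.assert_allclose(a, b, atol=1e-6)


class TestExtractLatent:
    @pytest.fixture(scope="class")
    def vae_and_stacks(self):
        stacks = _stacks(6, seed=4)
        vae = Vae(VaeConfig(input_channels=2, epochs=2, seed=4, **TOY))
        pretrain(vae, stacks)
        return vae, stacks

    def test_deterministic(self, vae_and_stacks):
        vae, stacks = vae_and_stacks
        a = extract_latent(vae, stacks[0], "pre_lesion").mu
        b = extract_latent(vae, stacks[0], "pre_lesion").mu
        np.testing.assert_array_equal(a, b)
        assert len(a) == 48

    def test_sensitive_to_distant_voxel(self, vae_and_stacks):
        vae, stacks = vae_and_stacks
        import copy
        other = copy.deepcopy(stacks[0])
        other.lesion[2, 1, 1, 0] = 1.0 - other.lesion[2, 1, 1, 0]
        a = extract_latent(vae, stacks[0], "pre_lesion").mu
        b = extract_latent(vae, other, "pre_lesion").mu
        assert not np.allclose(a, b)

    def test_bad_group_rejected(self, vae_and_stacks):
        vae, stacks = vae_and_stacks
        with pytest.raises(ValueError):
            extract_latent(vae, stacks[0], "mid_lesion")


class TestAssembleFeatures:
    @pytest.fixture(scope="class")
    def assembled(self):
        stacks = _stacks(4, seed=5)
        vae1 = Vae(VaeConfig(input_channels=2, epochs=1, seed=6, **TOY))
        vae2 = Vae(VaeConfig(input_channels=1, epochs=1, seed=6, **TOY))
        pretrain(vae1, stacks)
        pretrain(vae2, stacks)
        return stacks, vae1, vae2

    def test_default_192_with_four_groups(self, assembled):
        stacks, vae1, vae2 = assembled
        fv = assemble_mri_features(stacks[0], stacks[1], vae1, vae2)
        assert len(fv.values) == 192
        from collections import Counter
        assert Counter(fv.groups) == {"pre_lesion": 48, "post_lesion": 48,
                                      "pre_mask": 48, "post_mask": 48}

    def test_augmented_196(self, assembled):
        stacks, vae1, vae2 = assembled
        fv = assemble_mri_features(stacks[0], stacks[1], vae1, vae2,
                                   augment_scalars=True)
        assert len(fv.values) == 196

    def test_missing_timepoint_rejected(self, assembled):
        stacks, vae1, vae2 = assembled
        with pytest.raises(ValueError):
            assemble_mri_features(stacks[0], None, vae1, vae2)


def test_latents_separate_tumor_sizes_linear_probe():
    """Reconstruction-trained latents carry morphology: a linear probe on mu
    separates small-tumor from large-tumor stacks with AUC > 0.9."""
    from sklearn.linear_model import LogisticRegression
    from kpsfusion.evaluation import compute_metrics
    small = _stacks(20, seed=7, grid=(28, 24, 24), radius=2.0)
    large = _stacks(20, seed=8, grid=(28, 24, 24), radius=5.0)
    vae = Vae(VaeConfig(input_channels=2, epochs=6, seed=9,
                        input_shape=(24, 24, 24), pool=(2, 4, 4),
                        hidden_widths=(32,)))
    pretrain(vae, small + large)
    mu = np.stack([extract_latent(vae, s, "pre_lesion").mu for s in small + large])
    y = np.array([0] * 20 + [1] * 20)
    probe = LogisticRegression(max_iter=2000).fit(mu, y)
    auc = compute_metrics(y, probe.predict_proba(mu)[:, 1])["auc"]
    assert auc > 0.9
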