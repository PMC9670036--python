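"""Contrastive loss closed forms, augmentation contracts, training progress."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from patchgraph.autograd import Tensor
from patchgraph.contrastive import (AugmentationPolicy, EmbeddingBatch,
                                    FeatureExtractor, PretrainConfig,
                                    augment_pair, cosine_sim, extract_features,
                                    nt_xent_loss, pretrain)


class TestCosineSim:
    def test_known_values(self):
        assert cosine_sim([1, 0], [1, 0]) == pytest.approx(1.0)
        assert cosine_sim([1, 0], [0, 1]) == pytest.approx(0.0)
        assert cosine_sim([1, 1], [1, 0]) == pytest.approx(1 / np.sqrt(2))

    def test_scale_invariance_and_symmetry(self, rng):
        u, v = rng.normal(size=4), rng.normal(size=4)
        assert cosine_sim(u, v) == pytest.approx(cosine_sim(v, u))
        assert cosine_sim(3.7 * u, v) == pytest.approx(cosine_sim(u, v))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="undefined similarity"):
            cosine_sim([0, 0], [1, 0])


class TestNTXent:
    def test_single_pair_gives_zero(self):
        """K=1: the denominator contains only the positive partner."""
        z = np.array([[1.0, 2.0], [-0.3, 0.4]])
        assert nt_xent_loss(z, tau=0.5).item() == pytest.approx(0.0, abs=1e-6)

    def test_identical_embeddings_closed_form(self):
        """All 2K vectors equal: every similarity is 1, loss = log(2K-1)."""
        z = np.tile([0.6, -0.8], (8, 1))  # K = 4
        assert nt_xent_loss(z, tau=0.5).item() == pytest.approx(np.log(7), abs=1e-6)

    def test_orthogonal_negatives_closed_form(self):
        """K=2, tau=0.5, identical positives, orthogonal negatives."""
        z = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        expected = -np.log(np.exp(2) / (np.exp(2) + 2))
        assert nt_xent_loss(z, tau=0.5).item() == pytest.approx(expected, abs=1e-6)

    def test_rotation_invariance(self, rng):
        z = rng.normal(size=(6, 3))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0],
                      [0, 0, 1.0]])
        a = nt_xent_loss(z, tau=0.3).item()
        b = nt_xent_loss(z @ R.T, tau=0.3).item()
        assert a == pytest.approx(b, abs=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=1, max_value=5), st.integers(0, 10_000))
    def test_loss_nonnegative(self, K, seed):
        z = np.random.default_rng(seed).normal(size=(2 * K, 4))
        assert nt_xent_loss(z, tau=0.5).item() >= -1e-9

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        z0 = rng.normal(size=(4, 3))  # 2K = 4

        def f(z):
            return nt_xent_loss(Tensor(z), tau=0.5).item()

        t = Tensor(z0.copy(), requires_grad=True)
        nt_xent_loss(t, tau=0.5).backward()
        num = np.zeros_like(z0)
        eps = 1e-6
        for i in np.ndindex(z0.shape):
            z0[i] += eps
            fp = f(z0)
            z0[i] -= 2 * eps
            fm = f(z0)
            z0[i] += eps
            num[i] = (fp - fm) / (2 * eps)
        assert np.abs(t.grad - num).max() < 1e-4

    def test_invalid_arguments(self):
        z = np.ones((4, 2))
        with pytest.raises(ValueError):
            nt_xent_loss(z, tau=0.0)
        with pytest.raises(ValueError):
            EmbeddingBatch(f=None, z=z, pair_index=np.array([1, 0, 2, 3]))  # 2,3 unpaired... self-paired
        with pytest.raises(ValueError):
            nt_xent_loss(np.zeros((4, 2)), tau=0.5)  # zero vectors


class TestAugmentation:
    def test_identity_policy_is_noop(self, rng):
        patch = rng.integers(0, 255, size=(32, 32, 3), dtype=np.uint8)
        a, b = augment_pair(patch, AugmentationPolicy.identity(), rng_seed=4)
        assert np.array_equal(a, patch) and np.array_equal(b, patch)

    def test_deterministic_given_seed(self, rng):
        patch = rng.integers(0, 255, size=(32, 32, 3), dtype=np.uint8)
        policy = AugmentationPolicy()
        assert all(
            np.array_equal(x, y)
            for x, y in zip(augment_pair(patch, policy, 7), augment_pair(patch, policy, 7))
        )

    def test_crop_changes_intensity_sometimes(self):
        patch = np.zeros((32, 32, 3), dtype=np.uint8)
        patch[:16] = 255  # half black, half white
        policy = AugmentationPolicy(color_distortion_strength=0.0,
                                    blur_probability=0.0,
                                    crop_scale_range=(0.5, 0.5))
        changed = sum(
            not np.isclose(augment_pair(patch, policy, s)[0].mean(), patch.mean())
            for s in range(100)
        )
        assert changed > 0

    def test_degenerate_crop_range_rejected(self):
        with pytest.raises(ValueError, match="degenerate crop range"):
            AugmentationPolicy(crop_scale_range=(0.9, 0.5))


class TestPretrainAndExtract:
    def make_patches(self, n=16, seed=0):
        rng = np.random.default_rng(seed)
        return [rng.integers(0, 255, size=(32, 32, 3), dtype=np.uint8) for _ in range(n)]

    def test_one_step_deterministic(self):
        patches = self.make_patches()
        cfg = PretrainConfig(steps=1, batch_size=4, seed=42)
        ext1, _ = pretrain(patches, cfg)
        ext2, _ = pretrain(patches, cfg)
        s1, s2 = ext1.backbone.state_dict(), ext2.backbone.state_dict()
        assert all(np.array_equal(s1[k], s2[k]) for k in s1)

    @staticmethod
    def make_textured_patches():
        """64 tiles drawn from fixture slides (structured, hence learnable)."""
        from patchgraph.synthetic import SyntheticSlideSpec, generate_slide

        patches = []
        for cls, seed in [("normal", 0), ("tumor_A", 1), ("tumor_B", 2), ("normal", 3)]:
            spec = SyntheticSlideSpec(f"{cls}{seed}", 4, 4, 32, cls,
                                      lesion_fraction=0.4, seed=seed)
            slide, _, _ = generate_slide(spec)
            for r in range(1, 5):
                for c in range(1, 5):
                    patches.append(slide.pixels[r * 32:(r + 1) * 32, c * 32:(c + 1) * 32])
        return patches

    def test_loss_decreases_majority_of_seeds(self):
        patches = self.make_textured_patches()
        wins = 0
        for seed in (0, 1, 2):
            cfg = PretrainConfig(steps=50, batch_size=8, seed=seed)
            _, losses = pretrain(patches, cfg)
            wins += np.mean(losses[-5:]) < losses[0]
        assert wins >= 2

    def test_projection_head_stripped(self):
        ext, _ = pretrain(self.make_patches(4), PretrainConfig(steps=1, batch_size=2, seed=0))
        assert ext.projection_head is None
        with pytest.raises(RuntimeError):
            ext.project(np.zeros((1, 32, 32, 3), dtype=np.uint8))

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            pretrain([], PretrainConfig(steps=1))

    def test_extract_features_aligns_with_grid(self, tiny_extractor, tiny_cohort):
        from patchgraph.synthetic import generate_slide
        from patchgraph.tiling import tile_and_filter

        spec = tiny_cohort.specs[0]
        slide, _, _ = generate_slide(spec)
        grid = tile_and_filter(slide, spec.patch_size)
        F = extract_features(tiny_extractor, grid)
        assert F.shape == (len(grid), tiny_extractor.feature_dim)
        # duplicating a patch duplicates its row exactly (deterministic inference)
        single = tiny_extractor.extract(np.stack([grid.patches[0]] * 2))
        assert np.array_equal(single[0], single[1])

    def test_checkpoint_roundtrip(self, tiny_extractor, tmp_path):
        tiny_extractor.save(tmp_path / "ckpt", meta={"tau": 0.5})
        loaded = FeatureExtractor.load(tmp_path / "ckpt")
        x = np.zeros((1, 32, 32, 3), dtype=np.uint8)
        assert np.allclose(tiny_extractor.extract(x), loaded.extract(x))

    def test_contrastive_structure_separates_textures(self, tiny_extractor, tiny_cohort):
        """Augmentations of one texture stay closer than two distinct textures."""
        from patchgraph.synthetic import generate_slide

        spec_a = next(s for s in tiny_cohort.specs if s.class_label == "tumor_A")
        spec_n = next(s for s in tiny_cohort.specs if s.class_label == "normal")
        slide_a, mask_a, _ = generate_slide(spec_a)
        slide_n, _, _ = generate_slide(spec_n)
        ys, xs = np.nonzero(mask_a)
        lesion_patch = slide_a.pixels[ys.min():ys.min() + 64, xs.min():xs.min() + 64]
        normal_patch = slide_n.pixels[64:128, 64:128]
        v1, v2 = augment_pair(lesion_patch, AugmentationPolicy(), rng_seed=0)
        f = tiny_extractor.extract(np.stack([v1, v2, normal_patch]))
        same = cosine_sim(f[0], f[1])
        cross = cosine_sim(f[0], f[2])
        assert same > cross
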