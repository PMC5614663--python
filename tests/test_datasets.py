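"""Synthetic generator, augmentation and split-protocol behaviour."""

import numpy as np
import pytest

from gpdnet import (AugmentConfig, LabeledImageSet, SynthConfig, augment,
                    generate_synthetic_gpd, resize_to_input, split_train_test)
from gpdnet.datasets import CLASS_NAMES


class TestGenerator:
    def test_deterministic_per_seed_and_distinct_across_seeds(self):
        cfg = SynthConfig(n_per_class=10, seed=7, difficulty="easy")
        a = generate_synthetic_gpd(cfg)
        b = generate_synthetic_gpd(cfg)
        np.testing.assert_array_equal(a.images, b.images)
        np.testing.assert_array_equal(a.labels, b.labels)
        c = generate_synthetic_gpd(SynthConfig(n_per_class=10, seed=8,
                                               difficulty="easy"))
        assert not np.array_equal(a.images, c.images)

    def test_balanced_classes_and_value_range(self):
        ds = generate_synthetic_gpd(SynthConfig(n_per_class=15, seed=0))
        np.testing.assert_array_equal(ds.class_counts(), [15, 15, 15])
        assert ds.images.shape == (45, 32, 32, 3)
        assert ds.images.min() >= 0 and ds.images.max() <= 1
        assert ds.class_names == CLASS_NAMES

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(n_per_class=0)
        with pytest.raises(ValueError):
            SynthConfig(difficulty="impossible")

    def test_difficulty_controls_noise_level(self):
        easy = generate_synthetic_gpd(SynthConfig(10, seed=1, difficulty="easy"))
        hard = generate_synthetic_gpd(SynthConfig(10, seed=1, difficulty="hard"))
        # high-frequency energy (pixel-to-pixel differences) grows with noise
        def roughness(imgs):
            return float(np.abs(np.diff(imgs, axis=2)).mean())
        assert roughness(hard.images) > roughness(easy.images)


class TestAugment:
    def test_identity_config_reproduces_sources(self):
        ds = generate_synthetic_gpd(SynthConfig(n_per_class=4, seed=2))
        out = augment(ds, AugmentConfig(crop_sizes=(32,), max_translation=0,
                                        multiplier=1), seed=0)
        assert len(out) == len(ds)
        np.testing.assert_allclose(out.images, ds.images, atol=1e-6)

    def test_multiplier_and_label_preservation(self):
        ds = generate_synthetic_gpd(SynthConfig(n_per_class=5, seed=3,
                                                image_size=48))
        out = augment(ds, AugmentConfig(crop_sizes=(48, 40, 32),
                                        max_translation=4, multiplier=3), seed=1)
        assert len(out) == 3 * len(ds)
        np.testing.assert_array_equal(out.class_counts(), [15, 15, 15])
        assert out.images.shape[1:] == (32, 32, 3)

    def test_clinical_scale_per_class_totals(self):
        """1,331 sources expand to 3,673 outputs when per-class targets are
        388 -> 1,211; 467 -> 1,218; 476 -> 1,244 (placeholder pixels)."""
        rng = np.random.default_rng(0)
        sizes = (388, 467, 476)
        images = rng.random((sum(sizes), 8, 8, 3)).astype(np.float32)
        labels = np.repeat([0, 1, 2], sizes)
        sources = LabeledImageSet(images, labels)
        out = augment(sources, AugmentConfig(crop_sizes=(8,), max_translation=2,
                                             per_class_counts=(1211, 1218, 1244)),
                      seed=0)
        assert len(out) == 3673
        np.testing.assert_array_equal(out.class_counts(), [1211, 1218, 1244])

    def test_oversized_crop_rejected(self):
        ds = generate_synthetic_gpd(SynthConfig(n_per_class=2, seed=0))
        with pytest.raises(ValueError):
            augment(ds, AugmentConfig(crop_sizes=(475,)), seed=0)


class TestSplit:
    def test_partition_property_over_seeds(self):
        ds = generate_synthetic_gpd(SynthConfig(n_per_class=20, seed=5))
        key = ds.images.reshape(len(ds), -1).sum(axis=1)
        for seed in range(20):
            tr, te = split_train_test(ds, per_class_test=6, seed=seed)
            assert len(tr) + len(te) == len(ds)
            np.testing.assert_array_equal(te.class_counts(), [6, 6, 6])
            merged = np.sort(np.concatenate(
                [tr.images.reshape(len(tr), -1).sum(axis=1),
                 te.images.reshape(len(te), -1).sum(axis=1)]))
            np.testing.assert_allclose(merged, np.sort(key))

    def test_zero_holdout_returns_everything_as_train(self):
        ds = generate_synthetic_gpd(SynthConfig(n_per_class=4, seed=1))
        tr, te = split_train_test(ds, per_class_test=0, seed=0)
        assert len(te) == 0 and len(tr) == len(ds)

    def test_undersized_class_rejected(self):
        ds = generate_synthetic_gpd(SynthConfig(n_per_class=5, seed=1))
        with pytest.raises(ValueError):
            split_train_test(ds, per_class_test=5, seed=0)

    def test_clinical_counts_give_900_test_2773_train(self):
        sizes = (1211, 1218, 1244)
        images = np.zeros((sum(sizes), 4, 4, 3), dtype=np.float32)
        labels = np.repeat([0, 1, 2], sizes)
        ds = LabeledImageSet(images, labels)
        tr, te = split_train_test(ds, per_class_test=300, seed=0)
        assert len(te) == 900 and len(tr) == 2773


class TestResize:
    def test_identity_on_target_size(self):
        img = np.random.default_rng(0).random((32, 32, 3))
        np.testing.assert_allclose(resize_to_input(img), img, atol=1e-6)

    def test_constant_image_stays_constant(self):
        img = np.full((560, 475, 3), 0.62, dtype=np.float64)
        out = resize_to_input(img)
        assert out.shape == (32, 32, 3)
        np.testing.assert_allclose(out, 0.62, atol=1e-5)

    def test_output_shape_and_clamping(self):
        img = np.random.default_rng(1).random((7, 91, 3)) * 1.4
        out = resize_to_input(img)
        assert out.shape == (32, 32, 3)
        assert out.min() >= 0 and out.max() <= 1


class TestCalibration:
    def test_accuracy_ordering_easy_medium_hard(self):
        """Classifier accuracy is ordered easy >= medium >= hard on matched
        small training budgets (3 seeds, majority vote)."""
        from gpdnet import TrainConfig, build_gpdnet, train

        spec = build_gpdnet(3, True)
        votes_em, votes_mh = 0, 0
        for seed in range(3):
            accs = {}
            for diff in ("easy", "medium", "hard"):
                ds = generate_synthetic_gpd(
                    SynthConfig(n_per_class=120, seed=seed, difficulty=diff))
                tr, te = split_train_test(ds, per_class_test=30, seed=seed)
                res = train(spec, tr, TrainConfig(epochs=10, seed=seed),
                            test_set=te)
                accs[diff] = res.history.accuracy.iloc[-1]
            votes_em += accs["easy"] >= accs["medium"]
            votes_mh += accs["medium"] >= accs["hard"]
        assert votes_em >= 2 and votes_mh >= 2


class TestIO:
    def test_png_dir_round_trip(self, tmp_path):
        ds = generate_synthetic_gpd(SynthConfig(n_per_class=3, seed=4))
        root = ds.save_png_dir(tmp_path / "data")
        loaded = LabeledImageSet.load_png_dir(root, CLASS_NAMES)
        assert len(loaded) == len(ds)
        np.testing.assert_array_equal(np.sort(loaded.labels), np.sort(ds.labels))
        # 8-bit quantization bounds the round-trip error
        assert np.abs(np.sort(loaded.images.ravel())
                      - np.sort(ds.images.ravel())).max() <= 1 / 255

    def test_archive_round_trip_is_exact(self, tmp_path):
        ds = generate_synthetic_gpd(SynthConfig(n_per_class=3, seed=4))
        path = ds.save_archive(tmp_path / "ds.npz")
        loaded = LabeledImageSet.load_archive(path)
        np.testing.assert_array_equal(loaded.images, ds.images)
        np.testing.assert_array_equal(loaded.labels, ds.labels)
        assert loaded.class_names == ds.class_names
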