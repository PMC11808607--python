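"""Dataset loading, augmentation, and split protocols."""

import numpy as np
import pytest
from PIL import Image

from portnet.data import (AugmentParams, DataError, LabeledDataset, augment,
                          holdout_indices, holdout_split, kfold_split,
                          load_image_folder)


@pytest.fixture
def image_folder(tmp_path):
    rng = np.random.default_rng(0)
    for cname in ["adeno", "benign", "squamous"]:
        d = tmp_path / cname
        d.mkdir()
        for i in range(10):
            arr = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)
            Image.fromarray(arr).save(d / f"img_{i:02d}.png")
    return tmp_path


class TestLoadImageFolder:
    def test_counts_and_sorted_class_names(self, image_folder):
        ds = load_image_folder(image_folder)
        assert len(ds) == 30
        assert ds.class_names == ["adeno", "benign", "squamous"]
        assert list(ds.class_counts()) == [10, 10, 10]

    def test_unreadable_file_skipped_with_warning(self, image_folder, caplog):
        (image_folder / "adeno" / "broken.png").write_bytes(b"not an image")
        with caplog.at_level("WARNING"):
            ds = load_image_folder(image_folder)
        assert len(ds) == 30
        assert any("broken.png" in r.message for r in caplog.records)

    def test_empty_class_directory_raises_naming_class(self, image_folder):
        (image_folder / "empty_class").mkdir()
        with pytest.raises(DataError, match="empty_class"):
            load_image_folder(image_folder)

    def test_duplicate_filenames_across_classes_kept(self, image_folder):
        arr = np.zeros((8, 8, 3), dtype=np.uint8)
        Image.fromarray(arr).save(image_folder / "adeno" / "dup.png")
        Image.fromarray(arr).save(image_folder / "benign" / "dup.png")
        assert len(load_image_folder(image_folder)) == 32


class TestAugment:
    def test_degenerate_params_are_identity(self, rng):
        img = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)
        p = AugmentParams(max_rotation_deg=0, hflip_prob=0, brightness_range=(1, 1))
        np.testing.assert_array_equal(augment(img, p, rng), img)

    def test_same_seed_reproducible(self, rng):
        img = rng.integers(0, 256, (32, 32, 3)).astype(np.uint8)
        p = AugmentParams()
        a = augment(img, p, np.random.default_rng(5))
        b = augment(img, p, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_fixed_brightness_factor_scales_constant_image(self):
        img = np.full((16, 16, 3), 0.5)
        p = AugmentParams(max_rotation_deg=0, hflip_prob=0,
                          brightness_range=(0.5, 0.5))
        out = augment(img, p, np.random.default_rng(0))
        np.testing.assert_allclose(out, 0.25, atol=1e-12)

    def test_shape_and_range_preserved(self, rng):
        img = rng.integers(0, 256, (24, 24, 3)).astype(np.uint8)
        out = augment(img, AugmentParams(seed=1), rng)
        assert out.shape == img.shape and out.dtype == img.dtype

    def test_invalid_brightness_range_rejected(self, rng):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        with pytest.raises(DataError):
            augment(img, AugmentParams(brightness_range=(1.2, 1.1)), rng)


class TestHoldoutSplit:
    def test_balanced_3000_with_1250_holdout(self):
        labels = np.repeat([0, 1, 2], 1000)
        train, val, test = holdout_indices(labels, 1250, seed=0)
        assert len(val) == len(test) == 625
        assert len(train) == 1750
        for part in (val, test):
            counts = np.bincount(labels[part], minlength=3)
            assert counts.max() - counts.min() <= 1

    def test_zero_holdout(self):
        labels = np.repeat([0, 1, 2], 5)
        train, val, test = holdout_indices(labels, 0, seed=0)
        assert len(val) == len(test) == 0 and len(train) == 15

    def test_odd_holdout_rejected(self):
        with pytest.raises(DataError, match="even"):
            holdout_indices(np.repeat([0, 1], 10), 5, seed=0)

    @pytest.mark.parametrize("seed", range(0, 100, 7))
    def test_disjoint_and_covering(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 3, 90)
        train, val, test = holdout_indices(labels, 30, seed=seed)
        all_idx = np.concatenate([train, val, test])
        assert len(all_idx) == 90
        assert len(np.unique(all_idx)) == 90

    def test_dataset_level_wrapper(self, small_synthetic):
        ds, _ = small_synthetic
        tr, va, te = holdout_split(ds, 6, seed=1)
        assert len(va) == len(te) == 3
        assert len(tr) + len(va) + len(te) == len(ds)


class TestKFold:
    def test_balanced_30_items_k5(self):
        items = [(np.zeros((8, 8, 3), np.uint8), i % 3) for i in range(30)]
        ds = LabeledDataset(items, ["a", "b", "c"])
        fs, pairs = kfold_split(ds, k=5, seed=0)
        for tr, te in pairs:
            assert len(te) == 6
            assert np.bincount(ds.labels[te], minlength=3).tolist() == [2, 2, 2]
            assert np.intersect1d(tr, te).size == 0
        tested = np.concatenate([te for _, te in pairs])
        assert sorted(tested) == list(range(30))

    def test_class_smaller_than_k_raises(self):
        items = [(np.zeros((8, 8, 3), np.uint8), 0)] * 3 + \
                [(np.zeros((8, 8, 3), np.uint8), 1)] * 10
        ds = LabeledDataset(items, ["tiny", "big"])
        with pytest.raises(DataError, match="tiny"):
            kfold_split(ds, k=5, seed=0)

    def test_same_seed_identical_folds(self, small_synthetic):
        ds, _ = small_synthetic
        _, a = kfold_split(ds, k=5, seed=9)
        _, b = kfold_split(ds, k=5, seed=9)
        for (ta, ea), (tb, eb) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)
            np.testing.assert_array_equal(ea, eb)

    def test_stratification_bound_on_random_datasets(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 3, 101)
        items = [(np.zeros((8, 8, 3), np.uint8), int(l)) for l in labels]
        ds = LabeledDataset(items, ["a", "b", "c"])
        fs, pairs = kfold_split(ds, k=5, seed=3)
        per_class_per_fold = np.array([
            np.bincount(labels[te], minlength=3) for _, te in pairs])
        spread = per_class_per_fold.max(axis=0) - per_class_per_fold.min(axis=0)
        assert spread.max() <= 1
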