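"""Dataset loading, augmentation, and split protocols.

Datasets are directory-per-class image folders (the layout of the public
lung-histopathology image sets) or in-memory labeled image lists. Two split
protocols are provided: a stratified hold-out carve-out of ``n_holdout``
images split equally into validation and test, and stratified k-fold
cross-validation.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "DataError",
    "LabeledDataset",
    "FoldSplit",
    "AugmentParams",
    "load_image_folder",
    "augment",
    "holdout_indices",
    "holdout_split",
    "kfold_split",
    "write_manifest",
]


class DataError(ValueError):
    """Raised for malformed datasets or infeasible split requests."""


@dataclass
class LabeledDataset:
    """Labeled images: each item is (path or HxWx3 array, class id)."""

    items: list[tuple[object, int]]
    class_names: list[str]

    def __post_init__(self) -> None:
        k = len(self.class_names)
        for _, label in self.items:
            if not 0 <= label < k:
                raise DataError(f"label {label} outside 0..{k - 1}")

    def __len__(self) -> int:
        return len(self.items)

    @property
    def labels(self) -> np.ndarray:
        return np.array([lab for _, lab in self.items], dtype=np.int64)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=len(self.class_names))

    def load(self, i: int) -> np.ndarray:
        """Item ``i`` as an HxWx3 uint8 array."""
        src, _ = self.items[i]
        if isinstance(src, np.ndarray):
            return src
        with Image.open(src) as im:
            return np.asarray(im.convert("RGB"))

    def subset(self, indices) -> "LabeledDataset":
        return LabeledDataset([self.items[int(i)] for i in indices], self.class_names)


@dataclass
class FoldSplit:
    """Item-index -> fold-id assignment for k-fold cross-validation."""

    fold_assignments: np.ndarray
    k: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignments != fold)


_IMAGE_SUFFIXES = {".jpg", ".jpeg", ".png", ".bmp", ".tif", ".tiff"}


def load_image_folder(root) -> LabeledDataset:
    """Read a directory-per-class image folder.

    Class ids follow the sorted subdirectory names; items are sorted by path,
    so loading is deterministic. Unreadable files are skipped with a logged
    warning; an empty class directory is an error.
    """
    root = Path(root)
    if not root.is_dir():
        raise DataError(f"dataset root {root} is not a directory")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise DataError(f"no class subdirectories under {root}")
    items: list[tuple[object, int]] = []
    for label, cdir in enumerate(class_dirs):
        n_before = len(items)
        for path in sorted(cdir.iterdir()):
            if path.suffix.lower() not in _IMAGE_SUFFIXES:
                continue
            try:
                with Image.open(path) as im:
                    im.verify()
            except (UnidentifiedImageError, OSError) as exc:
                logger.warning("skipping unreadable image %s: %s", path, exc)
                continue
            items.append((str(path), label))
        if len(items) == n_before:
            raise DataError(f"class directory {cdir.name!r} contains no readable images")
    return LabeledDataset(items, [d.name for d in class_dirs])


@dataclass
class AugmentParams:
    """Stochastic training-time augmentation: rotation, flip, brightness."""

    max_rotation_deg: float = 15.0
    hflip_prob: float = 0.5
    brightness_range: tuple[float, float] = (0.8, 1.2)
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.brightness_range
        if not 0.0 <= lo <= hi:
            raise DataError(f"brightness_range must satisfy 0 <= lo <= hi, got ({lo}, {hi})")
        if not 0.0 <= self.hflip_prob <= 1.0:
            raise DataError(f"hflip_prob must be in [0,1], got {self.hflip_prob}")
        if self.max_rotation_deg < 0:
            raise DataError("max_rotation_deg must be non-negative")


def augment(img: np.ndarray, p: AugmentParams,
            rng: np.random.Generator) -> np.ndarray:
    """Apply one random rotation / horizontal flip / brightness draw.

    The rotation angle is uniform in +-max_rotation_deg with reflective fill,
    the flip fires with probability hflip_prob, and brightness is a single
    multiplicative factor uniform in brightness_range. Reproducible given the
    generator state; dimensions and value range are preserved.
    """
    p.validate()
    was_int = np.issubdtype(img.dtype, np.integer)
    unit = img.astype(np.float64) / 255.0 if was_int else img.astype(np.float64)

    angle = rng.uniform(-p.max_rotation_deg, p.max_rotation_deg)
    if angle != 0.0:
        unit = ndimage.rotate(unit, angle, axes=(1, 0), reshape=False,
                              order=1, mode="reflect")
    if rng.random() < p.hflip_prob:
        unit = unit[:, ::-1, :]
    lo, hi = p.brightness_range
    unit = unit * rng.uniform(lo, hi)

    unit = np.clip(unit, 0.0, 1.0)
    if was_int:
        return np.floor(unit * 255.0 + 0.5).astype(img.dtype)
    return unit.astype(img.dtype)


def _per_class_allocation(counts: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` draws across classes."""
    quota = counts * total / counts.sum()
    alloc = np.floor(quota).astype(int)
    remainder = quota - alloc
    for c in np.argsort(-remainder)[: total - alloc.sum()]:
        alloc[c] += 1
    if np.any(alloc > counts):
        raise DataError("hold-out request exceeds the size of a class")
    return alloc


def holdout_indices(labels: np.ndarray, n_holdout: int,
                    seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified (train, validation, test) index partition.

    ``n_holdout`` items are carved out proportionally per class, then split
    into equal validation and test halves (odd per-class carve-outs alternate
    between the two so the halves stay exactly n_holdout/2 each).
    """
    labels = np.asarray(labels)
    if n_holdout % 2 != 0:
        raise DataError(f"n_holdout must be even, got {n_holdout}")
    if n_holdout > len(labels):
        raise DataError("n_holdout exceeds dataset size")
    rng = np.random.default_rng(seed)
    counts = np.bincount(labels)
    alloc = _per_class_allocation(counts, n_holdout)
    val_idx, test_idx, train_idx = [], [], []
    toggle = 0
    for c, m in enumerate(alloc):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        carved, rest = idx[:m], idx[m:]
        train_idx.append(rest)
        half = m // 2
        if m % 2 == 0:
            val_idx.append(carved[:half])
            test_idx.append(carved[half:])
        else:
            extra_to_val = toggle == 0
            toggle ^= 1
            cut = half + (1 if extra_to_val else 0)
            val_idx.append(carved[:cut])
            test_idx.append(carved[cut:])
    train = np.sort(np.concatenate(train_idx)) if train_idx else np.array([], int)
    val = np.sort(np.concatenate(val_idx)) if val_idx else np.array([], int)
    test = np.sort(np.concatenate(test_idx)) if test_idx else np.array([], int)
    assert len(val) == len(test) == n_holdout // 2
    return train, val, test


def holdout_split(ds: LabeledDataset, n_holdout: int,
                  seed: int) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Dataset-level wrapper around :func:`holdout_indices`."""
    tr, va, te = holdout_indices(ds.labels, n_holdout, seed)
    return ds.subset(tr), ds.subset(va), ds.subset(te)


def kfold_split(ds: LabeledDataset, k: int = 5,
                seed: int = 0) -> tuple[FoldSplit, list[tuple[np.ndarray, np.ndarray]]]:
    """Stratified k-fold partition; every item is tested exactly once.

    Per-class counts across folds differ by at most one. Returns the fold
    assignment plus the (train_indices, test_indices) pair per fold.
    """
    if k < 2:
        raise DataError(f"k must be >= 2, got {k}")
    if len(ds.class_names) < 2:
        raise DataError("stratified k-fold needs at least 2 classes")
    labels = ds.labels
    counts = ds.class_counts()
    for c, n in enumerate(counts):
        if n < k:
            raise DataError(
                f"class {ds.class_names[c]!r} has {n} items, fewer than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2 ** 32))
    assignments = np.full(len(ds), -1, dtype=np.int64)
    pairs = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(ds)), labels)):
        assignments[te] = fold
        pairs.append((tr, te))
    return FoldSplit(assignments, k), pairs


def write_manifest(path, ds: LabeledDataset, split_of: dict[int, str],
                   fold_of: dict[int, int] | None = None) -> None:
    """Write a CSV manifest with columns path,label,split,fold."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label", "split", "fold"])
        for i, (src, label) in enumerate(ds.items):
            name = src if isinstance(src, str) else f"<memory:{i}>"
            fold = "" if fold_of is None else fold_of.get(i, "")
            writer.writerow([name, label, split_of.get(i, ""), fold])
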