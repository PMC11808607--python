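"""Training loop, 5-fold cross-validation runner, and external-test runner.

Defaults mirror the published protocol: Adam on softmax cross-entropy, batch
size 32, 10 epochs, learning rate 1e-5. Runs are deterministic given the
master seed: batch order, weight initialization, and per-fold seeds all
derive from it. Every cross-validation fold trains a fresh model on the k-1
training folds and is evaluated once on the held-out fold; train/test index
disjointness is asserted on every fold.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.transform import resize as _resize

from . import nn
from .config import ArchitectureConfig
from .data import AugmentParams, DataError, LabeledDataset, augment, kfold_split
from .metrics import (CVSummary, MetricsReport, RocCurve, ConfusionCounts,
                      confusion, cv_report, roc_auc, scalar_metrics)
from .model import PortNet, build_model
from .preprocessing import PreprocessParams, preprocess_pipeline

__all__ = [
    "TrainConfig",
    "RunManifest",
    "CVResult",
    "dataset_to_arrays",
    "train",
    "run_crossval",
    "run_external_test",
]


@dataclass
class TrainConfig:
    """Protocol hyperparameters.

    epochs=10, learning_rate=1e-5 and batch_size=32 are the published
    protocol; scaled-down demonstration runs raise the learning rate (1e-3)
    so the small network converges on small synthetic sets within a few
    epochs.
    """

    epochs: int = 10
    learning_rate: float = 1e-5
    batch_size: int = 32
    seed: int = 0
    optimizer: str = "adam"
    input_size: int = 224
    averaging: str = "macro"

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.averaging not in ("micro", "macro"):
            raise ValueError("averaging must be 'micro' or 'macro'")


@dataclass
class RunManifest:
    """Traceability record: config, seeds, per-epoch losses, metrics."""

    config: dict
    seed: int
    epoch_losses: list[float] = field(default_factory=list)
    val_metrics: list[dict] = field(default_factory=list)
    wall_seconds: float = 0.0
    artifacts: dict = field(default_factory=dict)


def dataset_to_arrays(ds: LabeledDataset, input_size: int,
                      preprocess: PreprocessParams | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Materialize a dataset as (N, 3, S, S) float32 in [0,1] plus labels.

    Applies the enhancement chain first when requested, then bilinear
    resizing to the model's input resolution.
    """
    xs = []
    for i in range(len(ds)):
        img = ds.load(i)
        if preprocess is not None:
            img = preprocess_pipeline(img, preprocess)
        unit = img.astype(np.float32) / 255.0 if np.issubdtype(img.dtype, np.integer) \
            else img.astype(np.float32)
        if unit.shape[0] != input_size or unit.shape[1] != input_size:
            unit = _resize(unit, (input_size, input_size), order=1,
                           preserve_range=True, anti_aliasing=True).astype(np.float32)
        xs.append(unit.transpose(2, 0, 1))
    return np.stack(xs), ds.labels


def _coerce(data, input_size: int) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, LabeledDataset):
        return dataset_to_arrays(data, input_size)
    x, y = data
    return np.ascontiguousarray(x, dtype=np.float32), np.asarray(y, dtype=np.int64)


def _eval_arrays(model: PortNet, x: np.ndarray, y: np.ndarray, averaging: str,
                 batch_size: int = 64) -> tuple[MetricsReport, ConfusionCounts,
                                                list[RocCurve], np.ndarray]:
    probs = np.concatenate([model.predict_proba(x[i:i + batch_size])
                            for i in range(0, len(x), batch_size)])
    preds = probs.argmax(axis=1)
    cc = confusion(y, preds, num_classes=model.config.num_classes)
    report = scalar_metrics(cc, averaging)
    try:
        curves, macro_auc = roc_auc(probs, y)
        report.auc = macro_auc
    except ValueError:
        curves = []
    return report, cc, curves, probs


def train(model: PortNet, train_data, val_data=None,
          cfg: TrainConfig | None = None,
          augment_params: AugmentParams | None = None) -> tuple[PortNet, RunManifest]:
    """Minimize softmax cross-entropy on the training set.

    ``train_data``/``val_data`` are either ``LabeledDataset`` or ``(X, y)``
    arrays. With ``augment_params`` set, each image receives a fresh random
    rotation/flip/brightness draw every epoch. Returns the trained model and
    a manifest with per-epoch mean losses and per-epoch validation metrics.
    """
    cfg = cfg or TrainConfig()
    cfg.validate()
    x, y = _coerce(train_data, cfg.input_size)
    if len(x) == 0:
        raise ValueError("empty training set")
    if y.max() >= model.config.num_classes:
        raise ValueError(
            f"label {y.max()} exceeds model's {model.config.num_classes} classes")
    val = _coerce(val_data, cfg.input_size) if val_data is not None else None

    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    manifest = RunManifest(config=asdict(cfg), seed=cfg.seed)
    t0 = time.time()
    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(x))
        losses = []
        for start in range(0, len(x), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = x[idx]
            if augment_params is not None:
                xb = np.stack([
                    augment(im.transpose(1, 2, 0), augment_params, rng).transpose(2, 0, 1)
                    for im in xb]).astype(np.float32)
            logits = model.forward(xb, train=True)
            loss, dlogits = nn.cross_entropy(logits, y[idx])
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        manifest.epoch_losses.append(float(np.mean(losses)))
        if val is not None:
            report, *_ = _eval_arrays(model, val[0], val[1], cfg.averaging)
            manifest.val_metrics.append(report.as_dict())
    if cfg.epochs > 0 and cfg.learning_rate > 0:
        model.recalibrate_bn(x, batch_size=max(cfg.batch_size, 64))
    manifest.wall_seconds = time.time() - t0
    return model, manifest


@dataclass
class CVResult:
    """Outcome of a k-fold cross-validation run."""

    per_fold: list[MetricsReport]
    summary: CVSummary
    fold_seeds: list[int]
    manifests: list[RunManifest]


def _fold_seed(master: int, fold: int) -> int:
    return int(np.random.SeedSequence([master, fold]).generate_state(1)[0] % (2 ** 31))


def run_crossval(ds: LabeledDataset, arch_config: ArchitectureConfig,
                 cfg: TrainConfig | None = None, k: int = 5,
                 augment_params: AugmentParams | None = None) -> CVResult:
    """Stratified k-fold protocol: fresh model per fold, test each item once."""
    cfg = cfg or TrainConfig()
    cfg.validate()
    x, y = _coerce(ds, cfg.input_size) if isinstance(ds, LabeledDataset) else _coerce(ds, cfg.input_size)
    wrapped = ds if isinstance(ds, LabeledDataset) else None
    if wrapped is None:
        raise DataError("run_crossval expects a LabeledDataset")
    _, pairs = kfold_split(wrapped, k=k, seed=cfg.seed)
    per_fold, seeds, manifests = [], [], []
    for fold, (tr_idx, te_idx) in enumerate(pairs):
        assert np.intersect1d(tr_idx, te_idx).size == 0, "train/test fold overlap"
        seed = _fold_seed(cfg.seed, fold)
        seeds.append(seed)
        fold_cfg = TrainConfig(**{**asdict(cfg), "seed": seed})
        model = build_model(arch_config, seed=seed)
        model, manifest = train(model, (x[tr_idx], y[tr_idx]), cfg=fold_cfg,
                                augment_params=augment_params)
        report, *_ = _eval_arrays(model, x[te_idx], y[te_idx], cfg.averaging)
        per_fold.append(report)
        manifests.append(manifest)
    return CVResult(per_fold=per_fold, summary=cv_report(per_fold),
                    fold_seeds=seeds, manifests=manifests)


def run_external_test(model: PortNet, test_data, cfg: TrainConfig | None = None
                      ) -> tuple[MetricsReport, ConfusionCounts, list[RocCurve]]:
    """Inference-only evaluation on a held-out set (no parameter updates)."""
    cfg = cfg or TrainConfig(averaging="micro")
    x, y = _coerce(test_data, cfg.input_size)
    if len(x) == 0:
        raise ValueError("empty test set")
    report, cc, curves, _ = _eval_arrays(model, x, y, cfg.averaging)
    return report, cc, curves
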