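"""Classification metrics: confusion counts, ACC/PRE/REC/F1, ROC/AUC, CV summary.

Scalar metrics follow the standard confusion-count definitions

    ACC = (TP + TN) / (TP + FP + TN + FN)        (pooled: trace / N)
    PRE = TP / (TP + FP)
    REC = TP / (TP + FN)
    F1  = 2 * PRE * REC / (PRE + REC)

computed one-vs-rest per class and combined either by pooling counts
("micro", which in single-label classification forces PRE = REC = ACC) or by
unweighted class means ("macro"). AUC uses the rank / Mann-Whitney
formulation with half credit for ties, equivalent to trapezoidal area under
the ROC curve with tied scores grouped; the macro AUC is the unweighted mean
over one-vs-rest classes. Cross-validation summaries report the fold mean and
a t-distribution 95% confidence half-width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "RocCurve",
    "confusion",
    "scalar_metrics",
    "roc_auc",
    "cv_report",
    "CVSummary",
]


@dataclass
class ConfusionCounts:
    """K x K confusion matrix (rows true, columns predicted) and the
    one-vs-rest TP/FP/FN/TN counts derived from it."""

    matrix: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def n(self) -> int:
        return int(self.matrix.sum())

    @property
    def k(self) -> int:
        return self.matrix.shape[0]


def confusion(labels, predictions, num_classes: int | None = None) -> ConfusionCounts:
    """Exact integer confusion counts from label/prediction lists."""
    labels = np.asarray(labels, dtype=np.int64)
    predictions = np.asarray(predictions, dtype=np.int64)
    if labels.shape != predictions.shape or labels.ndim != 1:
        raise ValueError(
            f"labels and predictions must be equal-length 1-D, got "
            f"{labels.shape} vs {predictions.shape}")
    k = num_classes or int(max(labels.max(initial=0), predictions.max(initial=0))) + 1
    if labels.size and (labels.min() < 0 or labels.max() >= k):
        raise ValueError("labels outside 0..K-1")
    matrix = np.zeros((k, k), dtype=np.int64)
    np.add.at(matrix, (labels, predictions), 1)
    tp = np.diag(matrix).copy()
    fp = matrix.sum(axis=0) - tp
    fn = matrix.sum(axis=1) - tp
    tn = matrix.sum() - tp - fp - fn
    return ConfusionCounts(matrix, tp, fp, fn, tn)


@dataclass
class MetricsReport:
    """ACC/PRE/REC/F1 (+ optional macro one-vs-rest AUC) with the averaging
    mode that produced them."""

    acc: float
    pre: float
    rec: float
    f1: float
    averaging: str
    n: int
    auc: float | None = None

    def as_dict(self) -> dict:
        d = {"acc": self.acc, "pre": self.pre, "rec": self.rec, "f1": self.f1,
             "averaging": self.averaging, "n": self.n}
        if self.auc is not None:
            d["auc"] = self.auc
        return d


def _f1(pre: float, rec: float) -> float:
    return 0.0 if pre + rec == 0 else 2.0 * pre * rec / (pre + rec)


def scalar_metrics(cc: ConfusionCounts, averaging: str = "macro") -> MetricsReport:
    """ACC plus micro- or macro-averaged PRE/REC/F1 from confusion counts."""
    if averaging not in ("micro", "macro"):
        raise ValueError(f"averaging must be 'micro' or 'macro', got {averaging!r}")
    n = cc.n
    if n == 0:
        raise ValueError("empty confusion matrix")
    acc = float(cc.tp.sum()) / n
    if averaging == "micro":
        tp, fp, fn = cc.tp.sum(), cc.fp.sum(), cc.fn.sum()
        pre = float(tp) / (tp + fp) if tp + fp else 0.0
        rec = float(tp) / (tp + fn) if tp + fn else 0.0
        f1 = _f1(pre, rec)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            pre_c = np.where(cc.tp + cc.fp > 0, cc.tp / (cc.tp + cc.fp), 0.0)
            rec_c = np.where(cc.tp + cc.fn > 0, cc.tp / (cc.tp + cc.fn), 0.0)
        f1_c = np.array([_f1(p, r) for p, r in zip(pre_c, rec_c)])
        pre, rec, f1 = float(pre_c.mean()), float(rec_c.mean()), float(f1_c.mean())
    return MetricsReport(acc=acc, pre=pre, rec=rec, f1=f1, averaging=averaging, n=n)


@dataclass
class RocCurve:
    """One-vs-rest ROC for one class: (FPR, TPR) points and thresholds."""

    class_id: int
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def _auc_rank(scores: np.ndarray, positive: np.ndarray) -> float:
    """Mann-Whitney AUC with average ranks (0.5 credit for ties)."""
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    ranks = stats.rankdata(scores)
    return float((ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_auc(scores: np.ndarray, labels) -> tuple[list[RocCurve], float]:
    """Per-class one-vs-rest ROC curves and the macro-average AUC.

    ``scores`` is an N x K matrix of class scores (probabilities or logits —
    AUC is rank-based, so any monotone rescaling is equivalent). A class with
    no positive or no negative examples has no defined AUC; it is excluded
    from the macro mean with a warning.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.ndim != 2 or scores.shape[0] != labels.shape[0]:
        raise ValueError("scores must be N x K aligned with labels")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    k = scores.shape[1]
    if k < 2:
        raise ValueError("need at least 2 classes")
    curves, aucs = [], []
    for c in range(k):
        positive = labels == c
        n_pos = int(positive.sum())
        if n_pos == 0 or n_pos == labels.size:
            warnings.warn(
                f"class {c} has no {'positive' if n_pos == 0 else 'negative'} "
                "examples; AUC undefined, excluded from the macro mean",
                stacklevel=2)
            continue
        auc_c = _auc_rank(scores[:, c], positive)
        fpr, tpr, thr = _sk_roc_curve(positive.astype(int), scores[:, c])
        curves.append(RocCurve(c, fpr, tpr, thr, auc_c))
        aucs.append(auc_c)
    if not aucs:
        raise ValueError("no class had a defined AUC")
    return curves, float(np.mean(aucs))


@dataclass
class CVSummary:
    """Per-metric fold mean and 95% CI half-width (t distribution)."""

    k: int
    stats: dict[str, tuple[float, float]] = field(default_factory=dict)

    def row(self) -> str:
        cells = [f"{name}: {m * 100:.2f}% +/- {hw * 100:.2f}%"
                 for name, (m, hw) in self.stats.items()]
        return f"{self.k}-fold CV  " + "  ".join(cells)


def cv_report(per_fold: list[MetricsReport]) -> CVSummary:
    """Summarize fold metrics as mean +/- t_{0.975,k-1} * sd / sqrt(k)."""
    k = len(per_fold)
    if k < 2:
        raise ValueError(f"need >= 2 folds, got {k}")
    tcrit = float(stats.t.ppf(0.975, k - 1))
    summary = CVSummary(k=k)
    metric_names = ["acc", "pre", "rec", "f1"]
    if all(r.auc is not None for r in per_fold):
        metric_names.append("auc")
    for name in metric_names:
        vals = np.array([getattr(r, name) for r in per_fold], dtype=np.float64)
        mean = float(vals.mean())
        half = tcrit * float(vals.std(ddof=1)) / np.sqrt(k)
        summary.stats[name] = (mean, half)
    return summary
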