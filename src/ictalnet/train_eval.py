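"""Training loop, loss functions, and the evaluation metric suite.

Training follows the published recipe: Adam at learning rate 0.01, batch
size 32, 50 epochs, binary cross-entropy on the two-way log-softmax output
(focal and hinge losses are available for comparison).  Evaluation reports
accuracy, sensitivity, specificity, precision, F1 and trapezoid-rule AUC,
per patient and macro-averaged — the cross-patient protocol: one model
trained on pooled patients, scored on each patient's held-out windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .autodiff import Tensor
from .nn import Adam
from .model import SeizureDetector, classify_scores

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    batch_size: int = 32
    learning_rate: float = 0.01
    epochs: int = 50
    loss: str = "bce"           # bce | focal | hinge
    focal_gamma: float = 2.0
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.epochs) <= 0 or self.learning_rate <= 0:
            raise ValueError("hyperparameters must be positive")
        if self.loss not in ("bce", "focal", "hinge"):
            raise ValueError(f"unknown loss kind {self.loss!r}")


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


# -- losses ----------------------------------------------------------------

def loss(log_probs: Tensor, labels: np.ndarray, kind: str = "bce",
         gamma: float = 2.0) -> Tensor:
    """Scalar training loss from (B, 2) log-probabilities.

    * ``bce``   — mean of -log p_label, the two-class cross-entropy (equal to
      binary cross-entropy on the ictal probability);
    * ``focal`` — mean of -(1 - p_label)^gamma log p_label;
    * ``hinge`` — mean of max(0, 1 - s m) with s = +-1 labels and
      m = log p1 - log p0, the logit margin.
    """
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    onehot = np.zeros(log_probs.shape, dtype=log_probs.data.dtype)
    onehot[np.arange(len(labels)), labels] = 1.0
    log_p_label = (log_probs * Tensor(onehot)).sum(axis=-1)
    if kind == "bce":
        return -log_p_label.mean()
    if kind == "focal":
        p = log_p_label.exp()
        return -((1.0 - p) ** gamma * log_p_label).mean()
    if kind == "hinge":
        dt = log_probs.data.dtype
        sign = Tensor((2.0 * labels - 1.0).astype(dt))
        margin = _logit_margin(log_probs)
        return (1.0 - sign * margin).maximum(Tensor(np.zeros(len(labels), dtype=dt))).mean()
    raise ValueError(f"unknown loss kind {kind!r}")


def _logit_margin(log_probs: Tensor) -> Tensor:
    sel = Tensor(np.array([[-1.0], [1.0]], dtype=log_probs.data.dtype))
    return (log_probs @ sel).reshape(log_probs.shape[0])


# -- training --------------------------------------------------------------

def train(model: SeizureDetector, features: np.ndarray, labels: np.ndarray,
          cfg: TrainConfig | None = None) -> list[float]:
    """Seeded mini-batch training; returns the per-epoch mean loss trace.

    ``features`` is (N, C, F, T); the set is expected to be class-balanced.
    Aborts with a diagnostic if the loss turns non-finite.
    """
    cfg = cfg or TrainConfig()
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if len(features) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(model.parameters(), lr=cfg.learning_rate)
    model.train()
    trace: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(features))
        epoch_losses: list[float] = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            log_p = model.forward(features[idx])
            batch_loss = loss(log_p, labels[idx], kind=cfg.loss, gamma=cfg.focal_gamma)
            value = float(batch_loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch + 1}, "
                    f"batch {i // cfg.batch_size + 1}")
            optimizer.zero_grad()
            batch_loss.backward()
            optimizer.step()
            epoch_losses.append(value)
        trace.append(float(np.mean(epoch_losses)))
        logger.info("epoch %d/%d loss %.4f", epoch + 1, cfg.epochs, trace[-1])
    recalibrate_batchnorm(model, features, batch_size=cfg.batch_size)
    model.eval()
    return trace


def recalibrate_batchnorm(model: SeizureDetector, features: np.ndarray,
                          batch_size: int = 32) -> None:
    """Recompute batch-norm running statistics under the final weights.

    During optimisation the exponential running estimates lag behind the
    moving weights (and see dropout noise), so inference-mode normalisation
    can be badly calibrated after a short, high-learning-rate run.  One pass
    over the training set with frozen weights, dropout off and cumulative
    averaging replaces the stale estimates with full-data statistics.
    """
    from .nn import BatchNorm2d, Dropout  # local import to avoid cycles
    bns = [m for m in model.modules() if isinstance(m, BatchNorm2d)]
    if not bns:
        return
    model.train()
    for m in model.modules():
        if isinstance(m, Dropout):
            m.training = False
    saved = [(bn.momentum) for bn in bns]
    for bn in bns:
        bn.momentum = None
        bn.reset_running_stats()
    for i in range(0, len(features), batch_size):
        model.forward(features[i:i + batch_size])
    for bn, mom in zip(bns, saved):
        bn.momentum = mom
    model.eval()


# -- metrics ---------------------------------------------------------------

def confusion(predictions: Sequence[int], labels: Sequence[int]) -> ConfusionCounts:
    """2x2 cross-tabulation with ictal (1) as the positive class."""
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    if not np.isin(labels, (0, 1)).all() or not np.isin(predictions, (0, 1)).all():
        raise ValueError("labels and predictions must be 0 or 1")
    return ConfusionCounts(
        tp=int(np.sum((predictions == 1) & (labels == 1))),
        fp=int(np.sum((predictions == 1) & (labels == 0))),
        tn=int(np.sum((predictions == 0) & (labels == 0))),
        fn=int(np.sum((predictions == 0) & (labels == 1))),
    )


def metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """ACC, SEN, SPE, precision, F1; a zero denominator yields None, not 0."""

    def ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    acc = ratio(c.tp + c.tn, c.tp + c.tn + c.fp + c.fn)
    sen = ratio(c.tp, c.tp + c.fn)
    spe = ratio(c.tn, c.tn + c.fp)
    pre = ratio(c.tp, c.tp + c.fp)
    if pre is None or sen is None or (pre + sen) == 0:
        f1 = None
    else:
        f1 = 2.0 * pre * sen / (pre + sen)
    return {"accuracy": acc, "sensitivity": sen, "specificity": spe,
            "precision": pre, "f1": f1}


@dataclass
class RocCurve:
    """(FPR, TPR) points per threshold, FPR-sorted, anchored at (0,0) and (1,1)."""
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[RocCurve, float]:
    """ROC curve and trapezoid-rule AUC.

    Thresholds sweep the midpoints between consecutive unique scores plus
    +-infinity anchors; a prediction is positive when score >= threshold.
    AUC = 1/2 sum (x_{i+1} - x_i)(y_i + y_{i+1}) over the FPR-sorted points.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC is undefined with a single class present")
    uniq = np.unique(scores)
    thresholds = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]])
    fpr = np.empty(len(thresholds))
    tpr = np.empty(len(thresholds))
    for i, theta in enumerate(thresholds):
        pred = scores >= theta
        tpr[i] = np.sum(pred & (labels == 1)) / n_pos
        fpr[i] = np.sum(pred & (labels == 0)) / n_neg
    order = np.lexsort((tpr, fpr))
    fpr, tpr, thresholds = fpr[order], tpr[order], thresholds[order]
    auc = 0.5 * float(np.sum((fpr[1:] - fpr[:-1]) * (tpr[:-1] + tpr[1:])))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds), auc


# -- cross-patient evaluation ---------------------------------------------

def evaluate(model: SeizureDetector,
             per_patient: Mapping[str, tuple[np.ndarray, np.ndarray]],
             threshold: float = 0.5) -> dict:
    """Per-patient metric rows plus a macro-averaged row.

    ``per_patient`` maps patient id -> (features (N, C, F, T), labels).
    Patients with an empty test set are skipped with a warning; metrics that
    are undefined for a patient are reported as None and excluded from the
    macro average.
    """
    rows: dict[str, dict] = {}
    for patient in sorted(per_patient):
        features, labels = per_patient[patient]
        if len(labels) == 0:
            logger.warning("patient %s has an empty test set; skipped", patient)
            continue
        scores = model.score(features)
        preds = classify_scores(scores, threshold)
        c = confusion(preds, labels)
        row = dict(metrics(c))
        try:
            _, auc = roc_auc(scores, labels)
        except ValueError:
            auc = None
        row["auc"] = auc
        row["n_windows"] = int(len(labels))
        row["confusion"] = {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn}
        rows[patient] = row
    keys = ("accuracy", "sensitivity", "specificity", "precision", "f1", "auc")
    average: dict[str, float | None] = {}
    for key in keys:
        vals = [r[key] for r in rows.values() if r[key] is not None]
        average[key] = float(np.mean(vals)) if vals else None
    return {"patients": rows, "average": average,
            "n_patients": len(rows), "threshold": threshold}
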