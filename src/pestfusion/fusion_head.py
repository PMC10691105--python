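"""Shared classifier, soft/hard voting, branch losses, and metrics.

Both branches of the network classify through one FC layer + softmax so
the localized/fused features and the plain pooled features are scored in
the same embedding-to-class geometry.  At inference a group's rows of
class probabilities are averaged (soft voting) before the argmax; hard
voting (modal per-image label) is kept as an ablation baseline, with
ties deferred to the soft vote.  Metrics are overall accuracy plus
support-weighted one-vs-rest F1, from an explicit confusion matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .nn import log_softmax

logger = logging.getLogger(__name__)

__all__ = ["ProbabilityMatrix", "LossBundle", "MetricsReport", "classify",
           "soft_vote", "hard_vote", "branch_loss", "total_loss",
           "compute_metrics", "group_nll"]

_EPS = 1e-12


@dataclass
class ProbabilityMatrix:
    """n rows of class probabilities; each row sums to 1 within 1e-6."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("ProbabilityMatrix must be 2-D (n x m)")
        if (self.values < 0).any():
            raise ValueError("probabilities must be nonnegative")
        sums = self.values.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("each probability row must sum to 1")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class LossBundle:
    l_general: float
    l_improving: float

    @property
    def l_total(self) -> float:
        return self.l_general + self.l_improving


@dataclass
class MetricsReport:
    accuracy: float
    weighted_f1: float
    per_class: list[dict] = field(default_factory=list)
    confusion_counts: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "weighted_f1": self.weighted_f1,
                "per_class": self.per_class}


def classify(x: np.ndarray, weight: np.ndarray,
             bias: np.ndarray | None = None) -> ProbabilityMatrix:
    """Row-softmax of X W + b; both branches call this with shared weights."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if x.shape[1] != weight.shape[0]:
        raise ValueError(
            f"embedding dim {x.shape[1]} does not match FC input {weight.shape[0]}")
    z = x @ weight
    if bias is not None:
        z = z + bias
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return ProbabilityMatrix(e / e.sum(axis=1, keepdims=True))


def soft_vote(p: ProbabilityMatrix) -> tuple[int, np.ndarray]:
    """Average the rows; return (argmax class, mean probability vector)."""
    means = p.values.mean(axis=0)
    return int(np.argmax(means)), means


def hard_vote(labels: list[int],
              probabilities: ProbabilityMatrix | None = None) -> int:
    """Modal label; ties defer to the soft vote when probabilities exist."""
    if len(labels) == 0:
        raise ValueError("hard_vote needs at least one label")
    vals, counts = np.unique(labels, return_counts=True)
    winners = vals[counts == counts.max()]
    if len(winners) == 1:
        return int(winners[0])
    if probabilities is None:
        return int(winners.min())
    cls, _ = soft_vote(probabilities)
    return cls if cls in winners else int(winners.min())


def branch_loss(p: ProbabilityMatrix, labels) -> float:
    """Mean cross-entropy: -log of each row's probability at its truth."""
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 0 or labels.max() >= p.m:
        raise ValueError("labels outside [0, m)")
    probs = p.values[np.arange(p.n), labels]
    if (probs <= _EPS).any():
        logger.warning("true-class probability clamped at %g", _EPS)
        probs = np.maximum(probs, _EPS)
    return float(-np.log(probs).mean())


def total_loss(l_general: float, l_improving: float = 0.0) -> LossBundle:
    return LossBundle(float(l_general), float(l_improving))


def group_nll(logits: Tensor, labels) -> Tensor:
    """Differentiable mean negative log-likelihood for one group (training)."""
    labels = np.asarray(labels, dtype=int)
    logp = log_softmax(logits)
    onehot = np.zeros(logits.shape)
    onehot[np.arange(len(labels)), labels] = 1.0
    return -(logp * onehot).sum() * (1.0 / len(labels))


def compute_metrics(predictions, truths, m: int) -> MetricsReport:
    """Accuracy and support-weighted F1 from the m x m confusion matrix.

    Per-class precision/recall/F1 are one-vs-rest; a class with zero
    support contributes nothing to the weighted mean.  Undefined ratios
    (0/0) are reported as 0.
    """
    predictions = np.asarray(predictions, dtype=int)
    truths = np.asarray(truths, dtype=int)
    if predictions.size == 0:
        raise ValueError("compute_metrics needs at least one prediction")
    if predictions.shape != truths.shape:
        raise ValueError("predictions and truths must have equal length")
    conf = np.zeros((m, m), dtype=np.int64)
    np.add.at(conf, (truths, predictions), 1)
    total = conf.sum()
    accuracy = float(np.trace(conf) / total)
    per_class = []
    weighted = 0.0
    for c in range(m):
        tp = conf[c, c]
        fp = conf[:, c].sum() - tp
        fn = conf[c, :].sum() - tp
        support = int(conf[c, :].sum())
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        per_class.append({"label": c, "precision": float(prec),
                          "recall": float(rec), "f1": float(f1),
                          "support": support})
        weighted += support * f1
    weighted_f1 = float(weighted / total)
    return MetricsReport(accuracy, weighted_f1, per_class, conf)


def confusion_to_csv(report: MetricsReport, path) -> None:
    np.savetxt(path, report.confusion_counts, fmt="%d", delimiter=",")
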