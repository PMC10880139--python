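"""Performance and calibration metrics: balanced accuracy, ECE, one-vs-one AUROC."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import balanced_accuracy_score

__all__ = [
    "balanced_accuracy",
    "expected_calibration_error",
    "multiclass_auroc_ovo",
    "MetricsReport",
]


def balanced_accuracy(labels, predictions) -> float:
    """Mean per-class recall over the classes present in ``labels``."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.size == 0:
        raise ValueError("empty input")
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    return float(balanced_accuracy_score(labels, predictions))


def expected_calibration_error(probabilities, labels, n_bins: int = 10) -> float:
    """Confidence-binned gap between accuracy and mean confidence.

    Predictions are binned by their maximum predicted probability into
    ``n_bins`` equal-width bins over (0, 1];
    ECE = sum_b (|b| / n) * |acc(b) - conf(b)|.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    if p.ndim != 2 or p.shape[0] != y.shape[0]:
        raise ValueError("probabilities must be (n, Nc) matching labels")
    if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-5) or np.any(p < -1e-9):
        raise ValueError("probability rows must lie on the simplex")
    conf = p.max(axis=1)
    pred = p.argmax(axis=1)
    correct = (pred == y).astype(float)
    # bins (0, 1/n], (1/n, 2/n], ..., ((n-1)/n, 1]
    idx = np.ceil(conf * n_bins).astype(int) - 1
    idx = np.clip(idx, 0, n_bins - 1)
    n = y.shape[0]
    ece = 0.0
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue
        ece += (sel.sum() / n) * abs(correct[sel].mean() - conf[sel].mean())
    return float(ece)


def _pairwise_auc(scores_i: np.ndarray, scores_j: np.ndarray) -> float:
    """P(score of a class-i sample > score of a class-j sample) via ranks."""
    ni, nj = len(scores_i), len(scores_j)
    ranks = rankdata(np.concatenate([scores_i, scores_j]))
    return (ranks[:ni].sum() - ni * (ni + 1) / 2) / (ni * nj)


def multiclass_auroc_ovo(probabilities, labels) -> float:
    """Hand-Till one-vs-one multiclass AUROC.

    Unweighted mean over unordered class pairs (i, j) of
    (A(i|j) + A(j|i)) / 2, where A(i|j) is the probability that a class-i
    sample receives a higher class-i score than a class-j sample.  Pairs
    with an absent class are skipped with a warning.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    present = np.unique(y)
    if present.size < 2:
        raise ValueError("need at least 2 classes present")
    aucs = []
    for i, j in combinations(range(p.shape[1]), 2):
        sel_i, sel_j = y == i, y == j
        if not sel_i.any() or not sel_j.any():
            warnings.warn(f"class pair ({i}, {j}) skipped: a class is absent", stacklevel=2)
            continue
        a_ij = _pairwise_auc(p[sel_i, i], p[sel_j, i])
        a_ji = _pairwise_auc(p[sel_j, j], p[sel_i, j])
        aucs.append(0.5 * (a_ij + a_ji))
    return float(np.mean(aucs))


@dataclass
class MetricsReport:
    """Per-horizon metrics; ``None`` marks a horizon that could not be scored."""

    ba: list = field(default_factory=list)
    ece: list = field(default_factory=list)
    mauroc: list = field(default_factory=list)
    n_observed: list = field(default_factory=list)

    def horizon_average(self, metric: str, horizons=None) -> float:
        """Average of one metric over a window of horizon indices (default: all)."""
        values = getattr(self, metric)
        horizons = range(len(values)) if horizons is None else horizons
        selected = [values[t] for t in horizons if values[t] is not None]
        return float(np.mean(selected)) if selected else float("nan")

    def to_dict(self) -> dict:
        return {
            "ba": self.ba,
            "ece": self.ece,
            "mauroc": self.mauroc,
            "n_observed": self.n_observed,
        }

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "horizon": range(len(self.ba)),
                "ba": self.ba,
                "ece": self.ece,
                "mauroc": self.mauroc,
                "n_observed": self.n_observed,
            }
        )
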