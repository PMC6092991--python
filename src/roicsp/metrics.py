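"""Evaluation metrics: accuracy, Cohen's kappa, one-vs-rest sensitivity
and specificity, and paired method-comparison tables.

Cohen's kappa corrects agreement for chance:  k = (p_o - p_e)/(1 - p_e)
with observed agreement p_o and the marginal-product chance agreement
p_e.  For uniform marginals (balanced classes, unbiased predictions)
p_e = 1/K, giving the closed-form conversion
:func:`kappa_from_accuracy`.  Undefined rates (a class with no true
instances) are reported as missing, never silently as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix", "EvaluationReport", "confusion", "accuracy",
    "cohens_kappa", "kappa_from_accuracy", "sensitivity_specificity",
    "evaluate", "compare_methods", "round_half_up",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (display convention for report tables)."""
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass
class ConfusionMatrix:
    """Class x class counts; rows are true labels, columns predictions."""

    counts: np.ndarray
    class_order: list[int]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over class_order")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_order,
                            columns=self.class_order)


def confusion(y_true, y_pred, class_order=None) -> ConfusionMatrix:
    """Count matrix: counts[i, j] = #{true class_order[i], predicted [j]}."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if class_order is None:
        class_order = sorted(set(np.unique(y_true)) | set(np.unique(y_pred)))
    class_order = [int(c) for c in class_order]
    lookup = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if int(t) not in lookup or int(p) not in lookup:
            raise ValueError(f"label ({t}, {p}) outside class_order")
        counts[lookup[int(t)], lookup[int(p)]] += 1
    return ConfusionMatrix(counts=counts, class_order=class_order)


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction correct: trace / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement from the full confusion matrix."""
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm.counts) / n
    rows = cm.counts.sum(axis=1)
    cols = cm.counts.sum(axis=0)
    p_e = float(rows @ cols) / n ** 2
    if p_e >= 1.0:
        raise ValueError("degenerate marginals: chance agreement is 1, "
                         "kappa undefined")
    return float((p_o - p_e) / (1.0 - p_e))


def kappa_from_accuracy(acc: float, n_classes: int) -> float:
    """Uniform-chance kappa: (acc - 1/K) / (1 - 1/K)."""
    if not 0 <= acc <= 1:
        raise ValueError("accuracy must lie in [0, 1]")
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    p_e = 1.0 / n_classes
    return (acc - p_e) / (1.0 - p_e)


def sensitivity_specificity(cm: ConfusionMatrix, cls: int):
    """One-vs-rest true-positive and true-negative rate of one class.

    Returns (sensitivity, specificity); an undefined rate (no true
    positives+negatives of the relevant kind) comes back as NaN.
    """
    if cls not in cm.class_order:
        raise ValueError(f"class {cls} not in {cm.class_order}")
    i = cm.class_order.index(cls)
    tp = cm.counts[i, i]
    fn = cm.counts[i].sum() - tp
    fp = cm.counts[:, i].sum() - tp
    tn = cm.total - tp - fn - fp
    sens = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    spec = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    return float(sens), float(spec)


@dataclass
class EvaluationReport:
    """Bundle of accuracy, kappa and per-class rates for one evaluation."""

    confusion_matrix: ConfusionMatrix
    accuracy: float = field(init=False)
    kappa: float = field(init=False)
    sensitivity: dict[int, float] = field(init=False)
    specificity: dict[int, float] = field(init=False)

    def __post_init__(self):
        cm = self.confusion_matrix
        self.accuracy = accuracy(cm)
        self.kappa = cohens_kappa(cm)
        self.sensitivity, self.specificity = {}, {}
        for c in cm.class_order:
            s, p = sensitivity_specificity(cm, c)
            self.sensitivity[c] = s
            self.specificity[c] = p

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "sensitivity": {str(k): v for k, v in self.sensitivity.items()},
            "specificity": {str(k): v for k, v in self.specificity.items()},
            "confusion": self.confusion_matrix.counts.tolist(),
            "class_order": self.confusion_matrix.class_order,
        }


def evaluate(y_true, y_pred, class_order=None) -> EvaluationReport:
    """Full report straight from label vectors."""
    return EvaluationReport(confusion(y_true, y_pred, class_order))


def _mean_row(df: pd.DataFrame) -> pd.Series:
    """The stored Mean row when present, else the recomputed column mean."""
    if "Mean" in df.index:
        return df.loc["Mean"]
    return df.mean(axis=0)


def compare_methods(report_a: pd.DataFrame, report_b: pd.DataFrame,
                    decimals: int | None = 1) -> pd.DataFrame:
    """Per-column mean difference (b - a) between two per-subject tables.

    Both tables must share subjects (rows) and classes/metrics (columns);
    a stored ``Mean`` row, when present, is used as-is so published
    summary rows compare exactly as printed.  Rounding is half-up to
    ``decimals``; pass ``None`` to keep raw differences.
    """
    if list(report_a.index) != list(report_b.index):
        raise ValueError("subject rows of the two reports do not match")
    if list(report_a.columns) != list(report_b.columns):
        raise ValueError("columns of the two reports do not match")
    diff = report_b.astype(float) - report_a.astype(float)
    mean_diff = _mean_row(report_b.astype(float)) - _mean_row(
        report_a.astype(float))
    out = diff.loc[[i for i in diff.index if i != "Mean"]].copy()
    out.loc["MeanDiff"] = mean_diff
    if decimals is not None:
        out = out.map(lambda v: round_half_up(v, decimals))
    return out
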