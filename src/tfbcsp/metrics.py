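"""Confusion-matrix performance measures for two-class decoding.

Accuracy, positive/negative predictive value, sensitivity (TPR),
specificity (TNR) and Cohen's kappa = (Po - Pe) / (1 - Pe), with Pe the
marginal chance agreement. Ratios with a zero denominator are reported as
NaN with a warning, never silently zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ContractError

__all__ = ["ConfusionCounts", "MetricsReport", "confusion", "report"]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int
    positive_class: object

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    PPV: float
    NPV: float
    TPR: float
    TNR: float
    kappa: float
    Po: float
    Pe: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("accuracy", "PPV", "NPV", "TPR", "TNR", "kappa", "Po", "Pe")}


def confusion(y_true, y_pred, positive_class) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with the given label designated positive."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size < 1:
        raise ContractError("y_true and y_pred must be equal-length, non-empty")
    labels = set(np.unique(y_true)) | set(np.unique(y_pred))
    if len(labels) > 2:
        raise ContractError(f"more than two labels present: {sorted(map(str, labels))}")
    if positive_class not in labels:
        raise ContractError(f"positive_class {positive_class!r} not among labels")
    pos_t = y_true == positive_class
    pos_p = y_pred == positive_class
    return ConfusionCounts(
        TP=int(np.sum(pos_t & pos_p)),
        TN=int(np.sum(~pos_t & ~pos_p)),
        FP=int(np.sum(~pos_t & pos_p)),
        FN=int(np.sum(pos_t & ~pos_p)),
        positive_class=positive_class,
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                      RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def report(counts: ConfusionCounts) -> MetricsReport:
    """Evaluate the standard formulas on a confusion tally."""
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    n = counts.total
    if n <= 0:
        raise ContractError("empty confusion table")
    po = (tp + tn) / n
    # marginal chance agreement (Cohen)
    pe = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / (n * n)
    kappa = _ratio(po - pe, 1.0 - pe, "kappa")
    return MetricsReport(
        accuracy=po,
        PPV=_ratio(tp, tp + fp, "PPV"),
        NPV=_ratio(tn, tn + fn, "NPV"),
        TPR=_ratio(tp, tp + fn, "TPR"),
        TNR=_ratio(tn, tn + fp, "TNR"),
        kappa=kappa,
        Po=po,
        Pe=pe,
    )
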