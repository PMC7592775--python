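"""Three-category clinical classification of CVP and agreement statistics.

Mean CVP is classed against the clinical normal range 2-8 mmHg, i.e.
2.72-10.88 cmH2O: ``low`` below, ``normal`` within (boundaries inclusive),
``high`` above.  Agreement between true and predicted classes is summarized
by per-class sensitivity, overall accuracy and unweighted Cohen's kappa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .published import NORMAL_RANGE_CMH2O
from .signal_core import SignalValidationError

__all__ = ["CLASS_LABELS", "classify_cvp", "ConfusionReport", "confusion_report"]

CLASS_LABELS: Tuple[str, str, str] = ("low", "normal", "high")


def classify_cvp(value: float, bounds_cmh2o: Tuple[float, float] = NORMAL_RANGE_CMH2O) -> str:
    """Class label for a mean CVP in cmH2O; boundary values count as normal."""
    if not math.isfinite(value):
        raise SignalValidationError(f"non-finite CVP value: {value}")
    lo, hi = bounds_cmh2o
    if value < lo:
        return "low"
    if value > hi:
        return "high"
    return "normal"


@dataclass
class ConfusionReport:
    """3x3 confusion counts (true class x predicted class) and agreement stats.

    ``per_class_sensitivity`` entries are NaN for classes with no true
    members unless ``zero_for_empty`` was requested at construction time.
    """

    matrix: np.ndarray
    per_class_sensitivity: Tuple[float, float, float]
    overall_accuracy: float
    kappa: float
    labels: Tuple[str, ...] = CLASS_LABELS

    def to_text(self) -> str:
        lines = ["true\\pred\t" + "\t".join(self.labels)]
        for i, lab in enumerate(self.labels):
            lines.append(lab + "\t" + "\t".join(str(int(v)) for v in self.matrix[i]))
        for lab, s in zip(self.labels, self.per_class_sensitivity):
            lines.append(f"sensitivity[{lab}]\t{'n/a' if math.isnan(s) else f'{s:.3f}'}")
        lines.append(f"accuracy\t{self.overall_accuracy:.3f}")
        lines.append(f"kappa\t{self.kappa:.3f}")
        return "\n".join(lines)


def confusion_report(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    zero_for_empty: bool = False,
) -> ConfusionReport:
    """Confusion matrix, sensitivities, accuracy and Cohen's kappa.

    kappa = (p_o - p_e) / (1 - p_e), with expected agreement p_e from the
    products of the row/column marginals.  With ``zero_for_empty`` a class
    with no true members reports sensitivity 0.0 instead of NaN.
    """
    if len(true_labels) == 0 or len(true_labels) != len(predicted_labels):
        raise SignalValidationError("need equal-length, non-empty label sequences")
    index = {lab: i for i, lab in enumerate(CLASS_LABELS)}
    matrix = np.zeros((3, 3), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise SignalValidationError(f"unknown label in ({t!r}, {p!r})")
        matrix[index[t], index[p]] += 1
    total = matrix.sum()
    accuracy = float(np.trace(matrix)) / total

    sensitivities = []
    for i in range(3):
        row = matrix[i].sum()
        if row == 0:
            sensitivities.append(0.0 if zero_for_empty else float("nan"))
        else:
            sensitivities.append(float(matrix[i, i]) / row)

    p_o = accuracy
    p_e = float(np.sum(matrix.sum(axis=0) * matrix.sum(axis=1))) / total**2
    kappa = 1.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)

    return ConfusionReport(
        matrix=matrix,
        per_class_sensitivity=tuple(sensitivities),
        overall_accuracy=accuracy,
        kappa=float(kappa),
    )
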