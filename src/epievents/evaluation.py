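"""Multi-class performance metrics.

For four classes (spike, RonS, ripple, baseline) with P(i) positives and
N(i) = total - P(i) negatives per class:

* Acc      = 100 * sum_i TP(i) / sum_i P(i)
* Sens(i)  = 100 * TP(i) / P(i)            (true-positive rate)
* Spec(i)  = 100 * (1 - FP(i) / N(i))      (1 - false-positive rate)

Acc is algebraically the P(i)-weighted mean of the sensitivities.  Reports
are aggregated over randomizations as mean and sample SD (n-1 denominator).
Classes with P(i) = 0 (a subject may have no RonS at all) report sensitivity
as NaN and propagate it through aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .baseline_detector import CLASS_ORDER, EventLabel

N_CLASSES = len(CLASS_ORDER)
_INDEX = {lab: i for i, lab in enumerate(CLASS_ORDER)}


def _to_indices(labels) -> np.ndarray:
    out = np.empty(len(labels), dtype=int)
    for k, lab in enumerate(labels):
        out[k] = _INDEX[EventLabel(lab)] if not isinstance(lab, (int, np.integer)) else int(lab)
    return out


def confusion_matrix(true_labels, predicted_labels) -> np.ndarray:
    """4x4 count matrix; rows are true classes, columns predicted, in the
    fixed order (spike, rons, ripple, baseline)."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must have equal length")
    t = _to_indices(true_labels)
    p = _to_indices(predicted_labels)
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(cm, (t, p), 1)
    return cm


@dataclass
class EvalReport:
    """Confusion counts and the derived accuracy/sensitivity/specificity.

    When built by :func:`aggregate` the ``sd_*`` fields hold sample standard
    deviations over randomizations (0 for a single report).
    """

    confusion: np.ndarray
    acc: float
    sens: np.ndarray  # (4,) percent, NaN where P(i)=0
    spec: np.ndarray  # (4,) percent
    n_randomizations: int = 1
    sd_acc: float = 0.0
    sd_sens: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES))
    sd_spec: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES))

    @property
    def class_names(self) -> list[str]:
        return [lab.value for lab in CLASS_ORDER]

    def summary(self) -> str:
        lines = [f"Total accuracy: {self.acc:.1f} ({self.sd_acc:.1f}) %",
                 f"{'class':<10}{'Sens %':>14}{'Spec %':>14}"]
        for i, name in enumerate(self.class_names):
            s = "N/A" if np.isnan(self.sens[i]) else f"{self.sens[i]:.1f} ({self.sd_sens[i]:.1f})"
            lines.append(f"{name:<10}{s:>14}{self.spec[i]:>9.1f} ({self.sd_spec[i]:.1f})")
        return "\n".join(lines)


def compute_metrics(confusion: np.ndarray) -> EvalReport:
    """Apply the accuracy/sensitivity/specificity formulas to a confusion
    matrix of counts."""
    cm = np.asarray(confusion)
    if cm.shape != (N_CLASSES, N_CLASSES) or (cm < 0).any():
        raise ValueError("confusion must be a nonnegative 4x4 matrix")
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    P = cm.sum(axis=1).astype(float)
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0).astype(float) - tp
    N = total - P
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = 100.0 * tp / P          # NaN where P(i) = 0
        spec = 100.0 * (1.0 - fp / N)
    acc = 100.0 * tp.sum() / P.sum()
    return EvalReport(confusion=cm.copy(), acc=acc, sens=sens, spec=spec)


def aggregate(reports: list[EvalReport]) -> EvalReport:
    """Mean and sample SD of each metric across randomizations.

    NaN cells (classes absent from a subject) propagate as NaN.  A single
    report aggregates to itself with SD 0.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    accs = np.array([r.acc for r in reports])
    sens = np.stack([r.sens for r in reports])
    spec = np.stack([r.spec for r in reports])
    cm = np.sum([r.confusion for r in reports], axis=0)
    n = len(reports)
    ddof = 1 if n > 1 else 0
    return EvalReport(
        confusion=cm,
        acc=float(accs.mean()),
        sens=sens.mean(axis=0),
        spec=spec.mean(axis=0),
        n_randomizations=n,
        sd_acc=float(accs.std(ddof=ddof)) if n > 1 else 0.0,
        sd_sens=sens.std(axis=0, ddof=ddof) if n > 1 else np.zeros(N_CLASSES),
        sd_spec=spec.std(axis=0, ddof=ddof) if n > 1 else np.zeros(N_CLASSES),
    )
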