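"""ROC analysis, cost-slope operating point, and classification metrics.

The ROC curve plots the false positive rate against the true positive
rate as the decision threshold on the positive probability sweeps from
1 to 0; the AUC summarizes it (0.5 for a random classifier, 1 for a
perfect one).  The operating point is chosen by sliding a line of slope

    S = [Cost(P|N) - Cost(N|N)] / [Cost(N|P) - Cost(P|P)] * N / P

from the upper-left corner (FPR 0, TPR 1) down-right until it touches
the curve — equivalently, the curve vertex maximizing TPR - S * FPR.
At that threshold the standard confusion-matrix metrics are reported:
accuracy, positive predictive value, sensitivity, specificity and the
F-measure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "RocCurve",
    "OperatingPoint",
    "ConfusionMatrix",
    "MetricsReport",
    "Costs",
    "roc_curve",
    "optimal_operating_point",
    "confusion_at",
    "metrics",
]


@dataclass(frozen=True)
class RocCurve:
    """Thresholds (descending) with their FPR/TPR, plus trapezoid AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class Costs:
    """Misclassification costs; correct-classification costs default to 0."""

    cost_p_given_n: float = 1.0  # false positive
    cost_n_given_p: float = 1.0  # false negative
    cost_n_given_n: float = 0.0
    cost_p_given_p: float = 0.0


@dataclass(frozen=True)
class OperatingPoint:
    slope: float
    threshold: float
    fpr: float
    tpr: float


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    ppv: float
    sensitivity: float
    specificity: float
    f_measure: float
    f_variant: str


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """ROC over all distinct score thresholds plus sentinels; AUC by trapezoid."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(set(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


def optimal_operating_point(
    roc: RocCurve, costs: Costs, n_negative: int, n_positive: int
) -> OperatingPoint:
    """Cost-slope line sweep from (FPR 0, TPR 1); ties -> smallest FPR.

    Equivalent to maximizing TPR - S * FPR over the curve vertices.
    """
    denom = costs.cost_n_given_p - costs.cost_p_given_p
    numer = costs.cost_p_given_n - costs.cost_n_given_n
    if denom <= 0 or numer <= 0:
        raise ValueError(
            "costs must satisfy Cost(N|P) > Cost(P|P) and Cost(P|N) > Cost(N|N)"
        )
    if n_positive < 1 or n_negative < 1:
        raise ValueError("class counts must be positive")
    slope = numer / denom * n_negative / n_positive
    objective = roc.tpr - slope * roc.fpr
    # vertices tied within float tolerance count as equal; ties -> smallest FPR
    best = np.flatnonzero(objective >= objective.max() - 1e-12)
    i = best[np.argmin(roc.fpr[best])]
    return OperatingPoint(
        slope=float(slope),
        threshold=float(roc.thresholds[i]),
        fpr=float(roc.fpr[i]),
        tpr=float(roc.tpr[i]),
    )


def confusion_at(
    threshold: float,
    scores: Sequence[float],
    labels: Sequence[int],
    groups: Sequence[str] | None = None,
    strict: bool = False,
) -> ConfusionMatrix | dict[str, ConfusionMatrix]:
    """Confusion counts at a threshold, overall or per group (compound).

    Predicted positive iff score >= threshold (or strictly > with
    ``strict=True``).  With ``groups`` given, returns per-group matrices
    keyed by group plus an ``"__all__"`` overall matrix; per-group
    counts sum to the overall counts.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = scores > threshold if strict else scores >= threshold

    def tally(sel) -> ConfusionMatrix:
        p, l = pred[sel], labels[sel]
        return ConfusionMatrix(
            tp=int(np.sum(p & (l == 1))),
            fp=int(np.sum(p & (l == 0))),
            fn=int(np.sum(~p & (l == 1))),
            tn=int(np.sum(~p & (l == 0))),
        )

    if groups is None:
        return tally(np.ones(scores.size, dtype=bool))
    groups = np.asarray(groups, dtype=object)
    out = {g: tally(groups == g) for g in sorted(set(groups))}
    out["__all__"] = tally(np.ones(scores.size, dtype=bool))
    return out


def plot_roc(roc: RocCurve, out_path, operating_point: OperatingPoint | None = None):
    """Export the ROC curve (and optionally its operating point) as an image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(roc.fpr, roc.tpr, color="crimson", label=f"AUC = {roc.auc:.4f}")
    ax.plot([0, 1], [0, 1], color="gray", lw=0.8, ls="--")
    if operating_point is not None:
        ax.plot([operating_point.fpr], [operating_point.tpr], "o", color="black",
                label=f"operating point (S = {operating_point.slope:.2f})")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def metrics(cm: ConfusionMatrix, f_variant: str = "standard_f1") -> MetricsReport:
    """Acc/PPV/Sen/Spec/F from a confusion matrix; NaN where undefined.

    ``f_variant="standard_f1"`` (default) uses F = 2*PPV*Sen/(PPV+Sen);
    ``"text_literal"`` uses F = PPV*Sen/(PPV+Sen) — a harmonic-mean
    variant sometimes written without the factor 2 — kept behind a flag
    because the two disagree by exactly that factor (0.5 vs 1.0 for a
    perfect classifier).
    """
    if f_variant not in ("standard_f1", "text_literal"):
        raise ValueError("f_variant must be 'standard_f1' or 'text_literal'")

    def safe(num, den):
        return num / den if den > 0 else math.nan

    acc = safe(cm.tp + cm.tn, cm.total)
    ppv = safe(cm.tp, cm.tp + cm.fp)
    sen = safe(cm.tp, cm.tp + cm.fn)
    spec = safe(cm.tn, cm.tn + cm.fp)
    if math.isnan(ppv) or math.isnan(sen) or ppv + sen == 0:
        f = math.nan
    elif f_variant == "standard_f1":
        f = 2 * ppv * sen / (ppv + sen)
    else:
        f = ppv * sen / (ppv + sen)
    return MetricsReport(acc, ppv, sen, spec, f, f_variant)
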