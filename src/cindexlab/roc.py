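"""Empirical ROC curves, AUC and the Youden-optimal cut-off per marker.

The decision rule is "score >= threshold => predicted infection"; candidate
thresholds are the distinct observed scores plus a sentinel above the
maximum, so the curve always runs from (0, 0) to (1, 1). AUC is the
trapezoidal area, which for an empirical curve over all observed thresholds
equals the tie-corrected rank statistic U / (n_pos * n_neg); a brute-force
pairwise oracle is provided for that identity.

The reported cut-off maximizes Youden's J = sensitivity + specificity - 1,
with ties broken toward higher sensitivity (missing an infection is the
costly error in this setting) and then toward the lower threshold. Cut-offs
are reported as observed score values, the way clinical thresholds are
quoted, not interpolated midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .cindex import CIndexResult
from .cohort import BIOMARKERS, Cohort

#: Fixed marker order of the performance table.
MARKER_ORDER = ("pct", "crp", "il6", "cindex")


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC: thresholds (descending, +inf sentinel first), points, AUC."""

    marker: str
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int

    def sensitivity_specificity(self, i: int) -> tuple[float, float]:
        """(sensitivity, specificity) at threshold index ``i``."""
        return float(self.tpr[i]), float(1.0 - self.fpr[i])


@dataclass(frozen=True)
class CutoffPerformance:
    """One performance-table row: AUC and the selected operating point."""

    marker: str
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def _check_inputs(scores: Sequence[float], labels: Sequence[int]):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D collections")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both classes must be present; AUC is undefined otherwise")
    return s, y


def compute_roc(
    scores: Sequence[float],
    labels: Sequence[int],
    positive_high: bool = True,
    marker: str = "",
) -> ROCCurve:
    """Empirical ROC curve under the ">= threshold => infection" rule.

    With ``positive_high=False`` the rule flips to "<= threshold", for a
    hypothetical marker that decreases with infection.
    """
    s, y = _check_inputs(scores, labels)
    direction = 1.0 if positive_high else -1.0
    fpr, tpr, thr = _sk_roc_curve(y, direction * s, drop_intermediate=False)
    thresholds = direction * thr
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(
        marker=marker,
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        n_pos=int(y.sum()),
        n_neg=int(y.size - y.sum()),
    )


def auc_rank_oracle(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Brute-force pairwise AUC: (#{pos > neg} + 0.5 * #{pos = neg}) / (n_pos * n_neg).

    Quadratic in n; used as the independent check on the trapezoidal AUC.
    """
    s, y = _check_inputs(scores, labels)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((wins + 0.5 * ties) / (pos.size * neg.size))


def select_cutoff(curve: ROCCurve) -> CutoffPerformance:
    """Operating point maximizing Youden's J = sensitivity + specificity - 1.

    Ties on J are broken by higher sensitivity, then by lower threshold.
    J is a rational with denominator n_pos * n_neg, so candidates are ranked
    in exact integer arithmetic (true-positive and false-positive counts)
    rather than on the float curve values.
    """
    tp = np.rint(curve.tpr * curve.n_pos).astype(int)
    fp = np.rint(curve.fpr * curve.n_neg).astype(int)
    best = 0
    for i in range(1, len(tp)):
        # J * n_pos * n_neg = tp * n_neg - fp * n_pos, exactly
        j_i = tp[i] * curve.n_neg - fp[i] * curve.n_pos
        j_b = tp[best] * curve.n_neg - fp[best] * curve.n_pos
        if (j_i, tp[i], -curve.thresholds[i]) > (j_b, tp[best], -curve.thresholds[best]):
            best = i
    sens, spec = curve.sensitivity_specificity(best)
    return CutoffPerformance(
        marker=curve.marker,
        auc=curve.auc,
        cutoff=float(curve.thresholds[best]),
        sensitivity=sens,
        specificity=spec,
    )


def confusion_at_cutoff(
    scores: Sequence[float],
    labels: Sequence[int],
    cutoff: float,
    positive_high: bool = True,
) -> tuple[int, int, int, int]:
    """(tp, fp, tn, fn) under the decision rule at ``cutoff``."""
    s, y = _check_inputs(scores, labels)
    pred = (s >= cutoff) if positive_high else (s <= cutoff)
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    return tp, fp, tn, fn


def analyze_markers(
    cohort: Cohort, cindex_results: Sequence[CIndexResult]
) -> list[CutoffPerformance]:
    """Performance rows for PCT, CRP, IL-6 and the composite index, in that order.

    Infection (label 1) is the positive class throughout.
    """
    labels = cohort.labels
    rows = []
    for marker in MARKER_ORDER:
        if marker == "cindex":
            scores: Sequence[float] = [r.cindex for r in cindex_results]
        else:
            scores = cohort.values(marker)
        curve = compute_roc(scores, labels, marker=marker)
        rows.append(select_cutoff(curve))
    return rows


def marker_curves(
    cohort: Cohort, cindex_results: Sequence[CIndexResult]
) -> list[ROCCurve]:
    """Full ROC curves for the four markers (for export/plotting)."""
    labels = cohort.labels
    curves = []
    for marker in MARKER_ORDER:
        if marker == "cindex":
            scores: Sequence[float] = [r.cindex for r in cindex_results]
        else:
            scores = cohort.values(marker)
        curves.append(compute_roc(scores, labels, marker=marker))
    return curves
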