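"""Per-study diagnostic accuracy statistics from confusion matrices.

Orientation convention (fixed and documented): rows are true classes,
columns are predicted classes.  For binary and multi-class analyses the
*reference* category (healthy / least severe / largest, see
:func:`select_reference`) occupies row and column 0 after reordering, so
for a 2x2 matrix ``counts = [[TN, FP], [FN, TP]]``.

Provided measures: sensitivity, specificity, Youden index, empirical
accuracy, Cohen's kappa (binary and m-class), the diagnostic odds ratio
``SE*SP / ((1-SE)(1-SP))`` with the asymptotic variance of its log
(``1/TP + 1/FN + 1/TN + 1/FP``), and the Mantel-Haenszel pooling of the
``m - 1`` collapsed 2x2 tables of a multi-class matrix.  A continuity
correction of +0.5 on all four cells is applied whenever a cell of the
(collapsed) 2x2 table is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "StudyAccuracy",
    "binary_metrics",
    "log_odds_ratio",
    "kappa_multiclass",
    "mh_log_or",
    "multiclass_se_sp",
    "select_reference",
    "study_accuracy",
    "confusion_from_predictions",
]


@dataclass
class ConfusionMatrix:
    """m x m counts with class metadata.

    ``counts[i, j]``: samples of true class ``i`` predicted as ``j``.
    ``healthy`` flags disease-free classes; ``severity`` gives an
    ordinal severity rank (lower = less severe) where known.
    """

    counts: np.ndarray
    labels: list[str]
    healthy: dict[str, bool] = field(default_factory=dict)
    severity: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        m = len(self.labels)
        if self.counts.shape != (m, m):
            raise ValueError("counts must be square and match labels")
        if m < 2:
            raise ValueError("need at least 2 classes")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def m(self) -> int:
        return len(self.labels)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_binary_counts(cls, tp: int, fn: int, tn: int, fp: int,
                           labels: tuple[str, str] = ("negative", "positive")) -> "ConfusionMatrix":
        """Build a 2x2 matrix with the reference (negative) class first."""
        return cls(counts=np.array([[tn, fp], [fn, tp]]), labels=list(labels))

    def cells(self) -> tuple[int, int, int, int]:
        """(TP, FN, TN, FP) of a 2x2 matrix, reference class first."""
        if self.m != 2:
            raise ValueError("cells() requires a 2x2 matrix")
        (tn, fp), (fn, tp) = self.counts
        return int(tp), int(fn), int(tn), int(fp)

    def reordered(self, reference: int) -> "ConfusionMatrix":
        """Move the reference class to index 0 (rows and columns)."""
        order = [reference] + [i for i in range(self.m) if i != reference]
        return ConfusionMatrix(
            counts=self.counts[np.ix_(order, order)],
            labels=[self.labels[i] for i in order],
            healthy=self.healthy,
            severity=self.severity,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, **meta) -> "ConfusionMatrix":
        if list(frame.index) != list(frame.columns):
            raise ValueError("confusion table must have identical row and column labels")
        return cls(counts=frame.to_numpy(), labels=[str(c) for c in frame.columns], **meta)


@dataclass
class StudyAccuracy:
    """One study's accuracy summary (fractions; format with *100 for %)."""

    se: float
    sp: float
    youden: float
    accuracy: float
    kappa: float
    log_or: float
    var_log_or: float
    corrected: bool = False
    degenerate: bool = False

    def as_percent_row(self) -> dict[str, float]:
        return {
            "Sens. %": self.se * 100,
            "Spec. %": self.sp * 100,
            "Youden Index %": self.youden * 100,
            "Empirical Accuracy %": self.accuracy * 100,
            "Cohen's Kappa %": self.kappa * 100,
        }


def confusion_from_predictions(
    truth: Sequence, predicted: Sequence, labels: Sequence[str] | None = None, **meta
) -> ConfusionMatrix:
    """Tally a confusion matrix from aligned truth/prediction vectors."""
    t = [str(v) for v in truth]
    p = [str(v) for v in predicted]
    if len(t) != len(p):
        raise ValueError("truth and predictions differ in length")
    labs = [str(l) for l in labels] if labels is not None else sorted(set(t) | set(p))
    pos = {l: i for i, l in enumerate(labs)}
    counts = np.zeros((len(labs), len(labs)), dtype=np.int64)
    for a, b in zip(t, p):
        counts[pos[a], pos[b]] += 1
    return ConfusionMatrix(counts=counts, labels=labs, **meta)


def binary_metrics(cm: ConfusionMatrix) -> StudyAccuracy:
    """SE, SP, Youden, empirical accuracy and kappa of a 2x2 matrix.

    ``SE = TP/(TP+FN)``, ``SP = TN/(TN+FP)``, ``Y = SE+SP-1``,
    ``K = 2(TP*TN - FP*FN) / ((TP+FP)(TN+FP) + (TN+FN)(TP+FN))``.
    """
    tp, fn, tn, fp = cm.cells()
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both true classes must be non-empty")
    se = tp / (tp + fn)
    sp = tn / (tn + fp)
    youden = se + sp - 1.0
    accuracy = (tp + tn) / cm.n
    kappa = 2.0 * (tp * tn - fp * fn) / ((tp + fp) * (tn + fp) + (tn + fn) * (tp + fn))
    log_or, var, corrected = _log_or_cells(tp, fn, tn, fp)
    return StudyAccuracy(
        se=se, sp=sp, youden=youden, accuracy=accuracy, kappa=kappa,
        log_or=log_or, var_log_or=var, corrected=corrected,
    )


def _log_or_cells(tp: float, fn: float, tn: float, fp: float) -> tuple[float, float, bool]:
    corrected = 0 in (tp, fn, tn, fp)
    if corrected:
        tp, fn, tn, fp = tp + 0.5, fn + 0.5, tn + 0.5, fp + 0.5
    log_or = math.log((tp * tn) / (fn * fp))
    var = 1.0 / tp + 1.0 / fn + 1.0 / tn + 1.0 / fp
    return log_or, var, corrected


def log_odds_ratio(cm: ConfusionMatrix) -> tuple[float, float]:
    """Natural-log diagnostic odds ratio and its asymptotic variance.

    ``OR = SE*SP/((1-SE)(1-SP)) = TP*TN/(FN*FP)`` and
    ``var = 1/TP + 1/FN + 1/TN + 1/FP``; when any cell is zero, +0.5 is
    added to all four cells before both computations.
    """
    tp, fn, tn, fp = cm.cells()
    if (tp == 0 and fn == 0) or (tn == 0 and fp == 0) or (tp == 0 and fp == 0) or (fn == 0 and tn == 0):
        raise ValueError("two empty cells in the same margin")
    log_or, var, _ = _log_or_cells(tp, fn, tn, fp)
    return log_or, var


def kappa_multiclass(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement for an m x m confusion matrix.

    ``K = (sum a_ii - sum e_ii) / (N - sum e_ii)`` where the expected
    diagonal ``e_ii`` is the product of the i-th row and column margins
    over N.
    """
    a = cm.counts.astype(float)
    n = a.sum()
    if n == 0:
        raise ValueError("all-zero confusion matrix")
    observed = np.trace(a)
    expected = float((a.sum(axis=1) * a.sum(axis=0)).sum()) / n
    if n == expected:
        raise ValueError("degenerate margins: chance agreement equals total")
    return float((observed - expected) / (n - expected))


def mh_log_or(cm: ConfusionMatrix, reference: int = 0) -> tuple[float, float]:
    """Mantel-Haenszel pooled log odds ratio over collapsed 2x2 tables.

    With the reference class moved to index 0, each non-reference class
    ``i`` contributes the table ``[[a11, a1i], [ai1, aii]]``.  The MH
    estimate is ``log(sum(a11*aii/n_i) / sum(a1i*ai1/n_i))`` and the
    asymptotic variance divides the summed hypergeometric-style terms
    ``r1*r2*c1*c2 / ((n_i - 1) * n_i^2)`` by the product of the two MH
    sums.  The +0.5 continuity correction is applied per collapsed table
    when any of its four cells is zero.
    """
    cm = cm.reordered(reference)
    a = cm.counts.astype(float)
    num = den = var_num = 0.0
    for i in range(1, cm.m):
        t00, t01, t10, t11 = a[0, 0], a[0, i], a[i, 0], a[i, i]
        if 0.0 in (t00, t01, t10, t11):
            t00, t01, t10, t11 = t00 + 0.5, t01 + 0.5, t10 + 0.5, t11 + 0.5
        n_i = t00 + t01 + t10 + t11
        num += t00 * t11 / n_i
        den += t01 * t10 / n_i
        var_num += (t00 + t01) * (t10 + t11) * (t00 + t10) * (t01 + t11) / ((n_i - 1.0) * n_i ** 2)
    if num <= 0.0 or den <= 0.0:
        raise ValueError("degenerate tables")
    return math.log(num / den), var_num / (num * den)


def multiclass_se_sp(cm: ConfusionMatrix, log_or: float) -> tuple[float, float, bool]:
    """Multi-class SE/SP convention given a pooled log odds ratio.

    SP is the correctly classified proportion inside the reference
    category (row 0 after reordering); SE inverts the odds-ratio
    identity: ``SE = OR(1-SP) / (SP + OR(1-SP))``.  Returns
    ``(SE, SP, degenerate)`` where ``degenerate`` marks the SP = 1 limit
    (SE pinned to 0 by the formula despite a finite OR).
    """
    row = cm.counts[0].astype(float)
    if row.sum() == 0:
        raise ValueError("reference category is empty")
    sp = float(row[0] / row.sum())
    odds = math.exp(log_or)
    if sp >= 1.0:
        return 0.0, sp, True
    se = odds * (1.0 - sp) / (sp + odds * (1.0 - sp))
    return float(se), sp, False


def select_reference(
    labels: Sequence[str],
    sizes: Sequence[int],
    healthy: dict[str, bool] | None = None,
    severity: dict[str, float] | None = None,
) -> int:
    """Pick the reference category index.

    Preference order: a class flagged healthy; else the lowest severity
    rank; else the largest class; remaining ties go to the
    lexicographically first label.
    """
    if len(labels) < 2:
        raise ValueError("need at least 2 classes")
    healthy = healthy or {}
    severity = severity or {}
    idx = list(range(len(labels)))
    flagged = [i for i in idx if healthy.get(str(labels[i]), False)]
    if flagged:
        return min(flagged, key=lambda i: str(labels[i]))
    ranked = [i for i in idx if str(labels[i]) in severity]
    if ranked:
        return min(ranked, key=lambda i: (severity[str(labels[i])], str(labels[i])))
    return min(idx, key=lambda i: (-sizes[i], str(labels[i])))


def study_accuracy(cm: ConfusionMatrix, reference: int | None = None) -> StudyAccuracy:
    """Full accuracy summary for one study's confusion matrix.

    Binary matrices use the direct 2x2 formulas.  For m > 2 the matrix
    is reordered around the reference category (auto-selected from the
    class metadata when not given), kappa generalizes through the
    expected-diagonal form, empirical accuracy is the diagonal fraction,
    the pooled log OR comes from the Mantel-Haenszel estimator, and
    SE/SP follow the multi-class conventions.
    """
    if reference is None:
        reference = select_reference(
            cm.labels, cm.counts.sum(axis=1).tolist(), cm.healthy, cm.severity
        )
    cm = cm.reordered(reference)
    if cm.m == 2:
        return binary_metrics(cm)
    kappa = kappa_multiclass(cm)
    accuracy = float(np.trace(cm.counts) / cm.n)
    log_or, var = mh_log_or(cm, reference=0)
    se, sp, degenerate = multiclass_se_sp(cm, log_or)
    return StudyAccuracy(
        se=se, sp=sp, youden=se + sp - 1.0, accuracy=accuracy, kappa=kappa,
        log_or=log_or, var_log_or=var, degenerate=degenerate,
    )
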