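"""Evaluation metrics for 3-level ordinal severity assessment.

The central report is the macro (unweighted) average of one-vs-rest
sensitivity, specificity, positive/negative predictive value, balanced
accuracy and F-score over the three severity classes (none < mild <
moderate-severe).  Per-class metrics are computed in exact rational
arithmetic from the integer counts so that 2-decimal display rounding
(half-up) is free of binary floating-point boundary artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import stats as sps

N_CLASSES = 3
SEVERITY_NAMES = {0: "No deviation", 1: "Mild", 2: "Moderate to severe"}


@dataclass
class ConfusionMatrix3:
    """3x3 counts; rows = truth, columns = prediction."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (3, 3) or np.any(c < 0) or np.any(c != np.round(c)):
            raise ValueError("counts must be a 3x3 non-negative integer array")
        if c.sum() == 0:
            raise ValueError("empty confusion matrix")
        self.counts = c.astype(np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(truth: Sequence[int], predicted: Sequence[int]
                     ) -> ConfusionMatrix3:
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("label sequences differ in length")
    if not (np.isin(truth, (0, 1, 2)).all()
            and np.isin(predicted, (0, 1, 2)).all()):
        raise ValueError("labels must be in {0, 1, 2}")
    counts = np.zeros((3, 3), dtype=np.int64)
    for t, p in zip(truth, predicted):
        counts[t, p] += 1
    return ConfusionMatrix3(counts)


def _round2(x: Fraction | float | None) -> float | None:
    if x is None:
        return None
    if isinstance(x, Fraction):
        d = Decimal(x.numerator) / Decimal(x.denominator)
    else:
        d = Decimal(repr(float(x)))
    return float(d.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class MetricReport:
    """Macro one-vs-rest metrics; ``ppv`` is None when some class is never
    predicted (displayed as a dash)."""

    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float
    balanced_accuracy: float
    f_score: float
    _exact: dict | None = None

    def rounded(self) -> dict[str, float | None]:
        """Metrics rounded half-up to 2 decimals on the exact rationals."""
        src = self._exact or self.__dict__
        return {k: _round2(src[k]) for k in
                ("sensitivity", "specificity", "ppv", "npv",
                 "balanced_accuracy", "f_score")}


def macro_ovr_report(cm: ConfusionMatrix3) -> MetricReport:
    """Macro-averaged one-vs-rest metrics from a 3x3 count matrix.

    Per class c: TP = cm[c, c], FN = row c minus TP, FP = column c minus
    TP, TN = the rest.  If some class is never predicted (TP + FP = 0) its
    PPV is undefined — the macro PPV is then reported as None — and its
    F-score contributes 0.
    """
    c = cm.counts
    per = {"sensitivity": [], "specificity": [], "ppv": [], "npv": [],
           "balanced_accuracy": [], "f_score": []}
    ppv_undefined = False
    for k in range(3):
        tp = int(c[k, k])
        fn = int(c[k].sum()) - tp
        fp = int(c[:, k].sum()) - tp
        tn = cm.total - tp - fn - fp
        sens = Fraction(tp, tp + fn) if tp + fn else Fraction(0)
        spec = Fraction(tn, tn + fp) if tn + fp else Fraction(0)
        npv = Fraction(tn, tn + fn) if tn + fn else Fraction(0)
        per["sensitivity"].append(sens)
        per["specificity"].append(spec)
        per["npv"].append(npv)
        per["balanced_accuracy"].append((sens + spec) / 2)
        if tp + fp == 0:
            ppv_undefined = True
            per["f_score"].append(Fraction(0))
        else:
            ppv = Fraction(tp, tp + fp)
            per["ppv"].append(ppv)
            f1 = (2 * ppv * sens / (ppv + sens)
                  if ppv + sens > 0 else Fraction(0))
            per["f_score"].append(f1)
    exact = {k: sum(v) / 3 for k, v in per.items()
             if k not in ("ppv",)}
    exact["ppv"] = None if ppv_undefined else sum(per["ppv"]) / 3
    return MetricReport(
        sensitivity=float(exact["sensitivity"]),
        specificity=float(exact["specificity"]),
        ppv=None if exact["ppv"] is None else float(exact["ppv"]),
        npv=float(exact["npv"]),
        balanced_accuracy=float(exact["balanced_accuracy"]),
        f_score=float(exact["f_score"]),
        _exact=exact)


def percent_agreement(a: Sequence[int], b: Sequence[int]) -> float:
    a, b = np.asarray(a), np.asarray(b)
    if a.size == 0 or a.shape != b.shape:
        raise ValueError("need equal-length non-empty sequences")
    return 100.0 * float(np.mean(a == b))


def cohens_kappa(a: Sequence[int], b: Sequence[int]) -> float:
    """Cohen's kappa with chance agreement from the marginal products.

    When both raters are constant and identical (p_e = 1) kappa is defined
    as 1.0 by convention.
    """
    a, b = np.asarray(a), np.asarray(b)
    if a.size < 2 or a.shape != b.shape:
        raise ValueError("need >= 2 paired labels")
    cats = np.union1d(a, b)
    po = float(np.mean(a == b))
    pe = sum(float(np.mean(a == c)) * float(np.mean(b == c)) for c in cats)
    if pe >= 1.0 - 1e-15:
        return 1.0
    return (po - pe) / (1.0 - pe)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (mid-ranks on ties); NaN if degenerate."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size < 3 or x.shape != y.shape:
        raise ValueError("need equal-length sequences of >= 3 values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(sps.spearmanr(x, y).statistic)


def consensus_rating(labels: Sequence[int]) -> int:
    """Most common label among raters; ties go to the more severe class."""
    labels = np.asarray(labels)
    if labels.size < 2:
        raise ValueError("need at least 2 rater labels")
    counts = np.bincount(labels, minlength=3)
    best = counts.max()
    return int(max(np.flatnonzero(counts == best)))


_MERGE = {"none": 0, "mild": 1, "moderate": 2, "severe": 2}


def merge_severity(rating: str) -> int:
    """Collapse the 4-level scale: moderate and severe merge to level 2."""
    try:
        return _MERGE[rating.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown severity level {rating!r}") from None


def roc_ovr(proba: np.ndarray, truth: Sequence[int], cls: int
            ) -> tuple[np.ndarray, np.ndarray, float | None]:
    """One-vs-rest ROC for class ``cls`` by threshold sweep.

    Returns (fpr, tpr, area); area is None when the class is absent.
    """
    proba = np.asarray(proba, dtype=float)
    truth = np.asarray(truth)
    pos = truth == cls
    if not pos.any() or pos.all():
        return np.array([]), np.array([]), None
    scores = proba[:, cls]
    order = np.argsort(-scores, kind="stable")
    tp = np.concatenate([[0], np.cumsum(pos[order])])
    fp = np.concatenate([[0], np.cumsum(~pos[order])])
    # collapse tied scores to a single operating point
    distinct = np.concatenate([np.flatnonzero(np.diff(scores[order])) + 1,
                               [scores.size]])
    tpr = tp[np.concatenate([[0], distinct])] / pos.sum()
    fpr = fp[np.concatenate([[0], distinct])] / (~pos).sum()
    area = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, area
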