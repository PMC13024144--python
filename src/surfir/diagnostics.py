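"""L/S-ratio diagnostics: uncertainty propagation, grey zone, ROC.

The lecithin/sphingomyelin ratio is a lung-maturity marker: values *below*
the clinical cut-off (2.2 mol/mol) indicate surfactant immaturity, so a low
L/S is the test-positive (RDS-risk) call. Component prediction
uncertainties are symmetrised (the larger of the two 95% half-widths) and
propagated to the ratio by the first-order quotient rule

    h_{L/S} = (L/S) * sqrt((h_L/L)^2 + (h_S/S)^2)

with an interval-arithmetic (endpoint min/max) alternative available.
Cases whose uncertainty interval spans the cut-off are indeterminate (the
grey zone); under an intention-to-diagnose rule these count as false
negatives among reference positives and false positives among reference
negatives.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError, UndefinedMetricError
from .intervals import PredictionWithInterval

LS_THRESHOLD = 2.2

POSITIVE = "positive"
NEGATIVE = "negative"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class LsEstimate:
    l_hat: float
    s_hat: float
    h_l: float
    h_s: float
    ls_point: float
    ls_half_width: float


def ls_with_uncertainty(l: PredictionWithInterval, s: PredictionWithInterval,
                        method: str = "quotient") -> LsEstimate:
    """Propagate component half-widths to the ratio.

    ``quotient`` (default) is the first-order relative-error rule;
    ``interval`` takes the extreme endpoint ratios.
    """
    if s.point <= 0:
        raise DataError("sphingomyelin point estimate must be positive")
    h_l = l.half_width
    h_s = s.half_width
    if s.point - h_s <= 0:
        warnings.warn(
            "sphingomyelin interval reaches zero; ratio uncertainty is "
            "ill-conditioned", stacklevel=2)
    point = l.point / s.point
    if method == "quotient":
        rel_l = h_l / l.point if l.point != 0 else 0.0
        half = abs(point) * float(np.hypot(rel_l, h_s / s.point))
    elif method == "interval":
        s_lo = max(s.point - h_s, np.finfo(float).tiny)
        ratios = [(l.point - h_l) / (s.point + h_s), (l.point + h_l) / s_lo]
        half = max(max(ratios) - point, point - min(ratios))
    else:
        raise ConfigError("method must be 'quotient' or 'interval'")
    return LsEstimate(l_hat=l.point, s_hat=s.point, h_l=h_l, h_s=h_s,
                      ls_point=point, ls_half_width=half)


def grey_zone_bounds(threshold: float = LS_THRESHOLD,
                     half_width: float = 0.0) -> tuple[float, float]:
    """(threshold - h, threshold + h)."""
    if half_width < 0:
        raise ConfigError("grey-zone half-width must be >= 0")
    return threshold - half_width, threshold + half_width


def classify_case(ls_point: float, half_width: float,
                  threshold: float = LS_THRESHOLD) -> str:
    """Ternary call for one case.

    The closed interval [ls - h, ls + h] containing the threshold is
    indeterminate; entirely below is positive (RDS risk), entirely above
    negative.
    """
    if half_width < 0:
        raise ConfigError("half-width must be >= 0")
    if ls_point + half_width < threshold:
        return POSITIVE
    if ls_point - half_width > threshold:
        return NEGATIVE
    return INDETERMINATE


@dataclass(frozen=True)
class GreyZoneReport:
    threshold: float
    half_width: float
    tp: int
    fn: int
    tn: int
    fp: int
    n_indeterminate: int
    sensitivity: float
    specificity: float
    indeterminate_fraction: float

    def to_dict(self) -> dict:
        return dict(vars(self))


def intention_to_diagnose_confusion(classifications, labels,
                                    threshold: float = LS_THRESHOLD,
                                    half_width: float = float("nan")) -> GreyZoneReport:
    """Confusion counts with indeterminates counted as test failures.

    ``labels``: 1 = reference positive (RDS present), 0 = reference
    negative. Indeterminate calls become FN among positives and FP among
    negatives.
    """
    cls = list(classifications)
    y = np.asarray(labels, dtype=int)
    if len(cls) == 0:
        raise DataError("empty classification list")
    if len(cls) != y.size:
        raise DataError("classifications and labels differ in length")
    bad = {c for c in cls} - {POSITIVE, NEGATIVE, INDETERMINATE}
    if bad:
        raise DataError(f"unknown classification labels: {sorted(bad)}")
    tp = sum(1 for c, lab in zip(cls, y) if lab == 1 and c == POSITIVE)
    fn = sum(1 for c, lab in zip(cls, y) if lab == 1 and c != POSITIVE)
    tn = sum(1 for c, lab in zip(cls, y) if lab == 0 and c == NEGATIVE)
    fp = sum(1 for c, lab in zip(cls, y) if lab == 0 and c != NEGATIVE)
    n_ind = sum(1 for c in cls if c == INDETERMINATE)
    return GreyZoneReport(
        threshold=threshold, half_width=half_width,
        tp=tp, fn=fn, tn=tn, fp=fp, n_indeterminate=n_ind,
        sensitivity=sensitivity(tp, fn) if tp + fn else float("nan"),
        specificity=specificity(tn, fp) if tn + fp else float("nan"),
        indeterminate_fraction=n_ind / len(cls),
    )


def sensitivity(tp: int, fn: int) -> float:
    """TP / (TP + FN)."""
    if tp + fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no reference positives")
    return tp / (tp + fn)


def specificity(tn: int, fp: int) -> float:
    """TN / (TN + FP)."""
    if tn + fp == 0:
        raise UndefinedMetricError("specificity undefined: no reference negatives")
    return tn / (tn + fp)


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_curve(scores, labels) -> RocResult:
    """ROC for a *low-score-positive* test (low L/S indicates RDS).

    A case is called positive when its score is <= the decision threshold;
    sweeping the threshold over the unique scores (plus sentinels) traces
    TPR vs FPR, and the AUC is the trapezoidal integral — equal to the
    probability that a random positive scores below a random negative, ties
    counted half.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.size != y.size or s.size == 0:
        raise DataError("scores and labels must be equal-length and nonempty")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("ROC needs both classes present")
    thresholds = np.concatenate([[-np.inf], np.unique(s)])
    calls = s[None, :] <= thresholds[:, None]
    tpr = (calls & (y == 1)).sum(axis=1) / n_pos
    fpr = (calls & (y == 0)).sum(axis=1) / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def mean_test_half_width(half_widths) -> float:
    """Mean per-case ratio half-width; used as the global grey-zone
    half-width when projecting onto a reference cohort."""
    hw = np.asarray(half_widths, dtype=float)
    if hw.size == 0:
        raise DataError("no half-widths supplied")
    return float(hw.mean())


def apply_grey_zone(ls_values, labels, half_width: float,
                    threshold: float = LS_THRESHOLD) -> GreyZoneReport:
    """Project a fixed grey-zone half-width onto reference L/S values.

    Classifies each reference value with the global half-width, then applies
    the intention-to-diagnose accounting.
    """
    cls = [classify_case(v, half_width, threshold) for v in np.asarray(ls_values, float)]
    return intention_to_diagnose_confusion(cls, labels, threshold, half_width)
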