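"""Method-agreement statistics for angle measurements.

Implements the evaluation toolkit used to compare automated against manual
measurements: MAE with the SD of absolute errors, Bland-Altman bias and 95%
limits of agreement (bias +/- 1.96 * SD of the differences, ddof=1), Pearson
correlation with its two-sided p-value, and the 90-degree narrow/wide
classification summary. The difference direction is predicted - truth
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ca_core import classify_angle
from .errors import CaliperError

__all__ = [
    "AgreementReport",
    "BlandAltman",
    "mean_absolute_error",
    "bland_altman",
    "pearson_r",
    "classify_ca",
    "confusion_counts",
    "agreement_report",
]


def _pair(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.ndim != 1:
        raise CaliperError("pred and truth must be equal-length 1D sequences")
    if p.size == 0:
        raise CaliperError("empty input")
    return p, t


def mean_absolute_error(pred, truth) -> tuple[float, float]:
    """(mean, SD) of absolute errors |pred - truth|; SD uses ddof=1."""
    p, t = _pair(pred, truth)
    ae = np.abs(p - t)
    sd = float(np.std(ae, ddof=1)) if ae.size > 1 else 0.0
    return float(np.mean(ae)), sd


@dataclass
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray


def bland_altman(pred, truth) -> BlandAltman:
    """Bias and 95% limits of agreement of diffs = pred - truth."""
    p, t = _pair(pred, truth)
    if p.size < 2:
        raise CaliperError("Bland-Altman needs n >= 2")
    diffs = p - t
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return BlandAltman(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        means=(p + t) / 2.0,
        diffs=diffs,
    )


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson r and two-sided p (t transform, n-2 df)."""
    xv, yv = _pair(x, y)
    if xv.size < 3:
        raise CaliperError("Pearson correlation needs n >= 3")
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise CaliperError("constant input: correlation undefined")
    r, p = stats.pearsonr(xv, yv)
    return float(r), float(p)


def classify_ca(angles, threshold: float = 90.0) -> list[str]:
    """Label each angle "narrow" (< threshold) or "wide" (>= threshold)."""
    return [classify_angle(float(a), threshold) for a in np.asarray(angles, dtype=float)]


def confusion_counts(pred_angles, truth_angles, threshold: float = 90.0) -> dict:
    """Narrow/wide confusion matrix of predicted vs reference angles."""
    pl = classify_ca(pred_angles, threshold)
    tl = classify_ca(truth_angles, threshold)
    counts = {(a, b): 0 for a in ("narrow", "wide") for b in ("narrow", "wide")}
    for a, b in zip(pl, tl):
        counts[(a, b)] += 1
    mis = counts[("narrow", "wide")] + counts[("wide", "narrow")]
    return {
        "true_narrow": counts[("narrow", "narrow")],
        "true_wide": counts[("wide", "wide")],
        "pred_narrow_truth_wide": counts[("narrow", "wide")],
        "pred_wide_truth_narrow": counts[("wide", "narrow")],
        "misclassified": mis,
    }


@dataclass
class AgreementReport:
    """Summary of agreement between predicted and reference angles.

    Differences are predicted - reference; limits of agreement are
    bias +/- 1.96 * SD(diff, ddof=1).
    """

    mae: float
    mae_sd: float
    bias: float
    loa_low: float
    loa_high: float
    pearson_r: float
    pearson_p: float
    n: int
    misclassified: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def agreement_report(pred, truth, threshold: float = 90.0) -> AgreementReport:
    p, t = _pair(pred, truth)
    mae, mae_sd = mean_absolute_error(p, t)
    ba = bland_altman(p, t)
    r, pv = pearson_r(p, t)
    conf = confusion_counts(p, t, threshold)
    return AgreementReport(
        mae=mae,
        mae_sd=mae_sd,
        bias=ba.bias,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        pearson_r=r,
        pearson_p=pv,
        n=int(p.size),
        misclassified=conf["misclassified"],
    )
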