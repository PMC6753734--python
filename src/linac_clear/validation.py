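"""Confusion-matrix construction, ROC metrics, and margin-sweep validation.

Validation of a clearance predictor compares, pose by pose, the *calculated*
minimum distance against a *measured* one (physically, spring calipers;
here, a synthetic measurement generator with a calibrated error model).  A
pose is a predicted collision when ``calculated < margin`` and an actual
collision when the measured clearance is at (or below) the physical contact
threshold.  Sweeping the margin traces an ROC curve: larger margins trade
false positives (lost deliverable poses) for fewer false negatives
(undetected collisions).
"""

from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal

import numpy as np


class ValidationError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts: predicted collision vs physically observed collision."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclasses.dataclass(frozen=True)
class RocPoint:
    """Derived rates for one safety margin; all rates are fractions in [0, 1]."""

    margin_cm: float
    counts: ConfusionCounts
    accuracy: float
    npv: float
    sensitivity: float
    specificity: float
    fpr: float

    def as_percent_row(self) -> dict:
        c = self.counts
        return {
            "margin_cm": self.margin_cm,
            "tp": c.tp,
            "tn": c.tn,
            "fp": c.fp,
            "fn": c.fn,
            "accuracy_pct": percent(self.accuracy),
            "npv_pct": percent(self.npv),
            "sensitivity_pct": percent(self.sensitivity),
            "fpr_pct": percent(self.fpr),
        }


def percent(fraction: float, decimals: int = 1) -> float:
    """Percentage rounded half-up to ``decimals`` (table presentation rule)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(fraction * 100.0)).quantize(q, rounding=ROUND_HALF_UP))


def confusion(predicted_collision, actual_collision) -> ConfusionCounts:
    """Count TP/TN/FP/FN from parallel boolean label vectors."""
    pred = np.asarray(predicted_collision, dtype=bool)
    actual = np.asarray(actual_collision, dtype=bool)
    if pred.shape != actual.shape or pred.ndim != 1 or pred.size < 1:
        raise ValidationError("label vectors must be equal-length 1-d, n >= 1")
    return ConfusionCounts(
        tp=int(np.sum(pred & actual)),
        tn=int(np.sum(~pred & ~actual)),
        fp=int(np.sum(pred & ~actual)),
        fn=int(np.sum(~pred & actual)),
    )


def roc_metrics(
    c: ConfusionCounts, margin_cm: float = float("nan"), *, strict: bool = True
) -> RocPoint:
    """Derived ROC rates.

    ``accuracy = (TP+TN)/total``; ``NPV = TN/(TN+FN)`` (unity whenever
    FN = 0 and TN > 0); ``sensitivity = TP/(TP+FN)``; ``FPR = FP/(FP+TN)``.
    With ``strict`` (the default) undefined denominators raise rather than
    silently returning NaN; margin sweeps use the vacuous-truth convention
    instead (no negatives predicted -> NPV 1, no actual positives ->
    sensitivity 1), so saturated margins still yield a curve point.
    """
    if c.total <= 0:
        raise ValidationError("empty confusion matrix")
    if strict and c.tn + c.fn == 0:
        raise ValidationError("NPV undefined: TN + FN = 0")
    if strict and c.tp + c.fn == 0:
        raise ValidationError("sensitivity undefined: TP + FN = 0")
    neg = c.fp + c.tn
    return RocPoint(
        margin_cm=margin_cm,
        counts=c,
        accuracy=(c.tp + c.tn) / c.total,
        npv=(c.tn / (c.tn + c.fn)) if c.tn + c.fn else 1.0,
        sensitivity=(c.tp / (c.tp + c.fn)) if c.tp + c.fn else 1.0,
        specificity=(c.tn / neg) if neg else 1.0,
        fpr=(c.fp / neg) if neg else 0.0,
    )


@dataclasses.dataclass
class ClearanceComparison:
    """Per-pose measured vs calculated clearances over a (couch, gantry) grid."""

    couch_deg: np.ndarray
    gantry_deg: np.ndarray
    measured_cm: np.ndarray
    calculated_cm: np.ndarray

    def __post_init__(self) -> None:
        arrays = [
            np.asarray(a, dtype=float).reshape(-1)
            for a in (self.couch_deg, self.gantry_deg, self.measured_cm, self.calculated_cm)
        ]
        n = arrays[0].size
        if any(a.size != n for a in arrays) or n == 0:
            raise ValidationError("comparison arrays must be equal-length and non-empty")
        poses = set(zip(arrays[0].tolist(), arrays[1].tolist()))
        if len(poses) != n:
            raise ValidationError("duplicate (couch, gantry) poses in comparison")
        self.couch_deg, self.gantry_deg, self.measured_cm, self.calculated_cm = arrays

    @property
    def difference_cm(self) -> np.ndarray:
        """measured - calculated; negative means the model overpredicted the
        clearance (a collision could go undetected without a margin)."""
        return self.measured_cm - self.calculated_cm

    @property
    def n(self) -> int:
        return int(self.measured_cm.size)


def margin_sweep(
    comparison: ClearanceComparison,
    margins,
    physical_clearance_threshold: float = 0.0,
) -> list[RocPoint]:
    """One ROC point per safety margin.

    Actual collision: measured clearance at or below the physical contact
    threshold (default 0, i.e. contact).  Predicted collision: calculated
    clearance strictly below the margin.  The predicted-positive count is
    non-decreasing in the margin by construction.
    """
    actual = comparison.measured_cm <= physical_clearance_threshold
    points = []
    for margin in margins:
        predicted = comparison.calculated_cm < margin
        points.append(
            roc_metrics(
                confusion(predicted, actual), margin_cm=float(margin), strict=False
            )
        )
    return points


@dataclasses.dataclass(frozen=True)
class DifferenceStats:
    mean: float
    sd: float
    min: float
    max: float
    per_gantry: dict  # gantry_deg -> (min, median, max) across couch angles


def difference_stats(comparison: ClearanceComparison) -> DifferenceStats:
    """Population statistics of measured - calculated, plus the per-gantry
    min/median/max across couch angles used for radial summary plots."""
    diff = comparison.difference_cm
    if diff.size < 2:
        raise ValidationError("need >= 2 poses for a standard deviation")
    per_gantry = {}
    for g in np.unique(comparison.gantry_deg):
        d = diff[comparison.gantry_deg == g]
        per_gantry[float(g)] = (float(d.min()), float(np.median(d)), float(d.max()))
    return DifferenceStats(
        mean=float(diff.mean()),
        sd=float(diff.std(ddof=1)),
        min=float(diff.min()),
        max=float(diff.max()),
        per_gantry=per_gantry,
    )


def simulate_measurement(
    true_distance_cm,
    bias_cm: float = -0.2,
    sd_cm: float = 0.7,
    seed: int | np.random.Generator = 0,
    max_abs_error_cm: float | None = None,
) -> np.ndarray:
    """Synthetic caliper measurement: truth plus Gaussian error, floored at 0.

    Stands in for physical distance measurements.  The default error model
    (bias -0.2 cm, sd 0.7 cm) matches the agreement observed between
    calculated and physically measured clearances in end-to-end phantom
    testing of this class of software; ``max_abs_error_cm`` optionally clips
    the error to a worst-case band.  Deterministic per seed.
    """
    if sd_cm < 0:
        raise ValidationError("sd must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    true = np.asarray(true_distance_cm, dtype=float)
    err = rng.normal(bias_cm, sd_cm, size=true.shape) if sd_cm > 0 else np.full(true.shape, bias_cm)
    if sd_cm == 0 and bias_cm == 0:
        err = np.zeros(true.shape)
    if max_abs_error_cm is not None:
        err = np.clip(err, -max_abs_error_cm, max_abs_error_cm)
    return np.maximum(0.0, true + err)


def radial_difference_plot(stats: DifferenceStats, path):
    """Optional polar summary of per-gantry difference statistics (requires
    matplotlib; imported lazily)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    gantry = sorted(stats.per_gantry)
    theta = np.deg2rad(gantry)
    lo = [stats.per_gantry[g][0] for g in gantry]
    med = [stats.per_gantry[g][1] for g in gantry]
    hi = [stats.per_gantry[g][2] for g in gantry]
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ax.plot(theta, lo, label="min")
    ax.plot(theta, med, label="median")
    ax.plot(theta, hi, label="max")
    ax.set_title("measured - calculated clearance (cm) by gantry angle")
    ax.legend(loc="lower right")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
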