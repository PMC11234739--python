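"""The five validation-by-truncation statistics.

LR-method statistics compare partial-data EBV ``uhat_p`` (before the focal
animals had phenotypes) with whole-data EBV ``uhat_w``:

* bias ``mu_wp``      — mean of (uhat_p - uhat_w); 0 for unbiased predictions
* dispersion ``b_wp`` — slope of uhat_w on uhat_p; 1 when correctly dispersed
* ratio of accuracies ``rho_wp`` — their Pearson correlation (acc_p / acc_w)
* reliability ``rho2_cov_wp``    — S-centered cross-product over n * sigma_gi2

Predictivity compares uhat_p with adjusted phenotypes ``ystar`` and divides by
``h = sqrt(h2)`` to estimate prediction accuracy.

All centering quadratic forms with ``S = I - 11'/n`` are evaluated by explicit
mean-centering (S is never materialised).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StatisticEstimate",
    "bias",
    "dispersion",
    "ratio_accuracies",
    "reliability_estimate",
    "predictivity",
    "compute_statistics",
    "STATISTICS",
]

STATISTICS = ("bias", "dispersion", "ratio_accuracies", "reliability", "predictivity")


@dataclass(frozen=True)
class StatisticEstimate:
    name: str
    value: float
    n: int


def _center(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x - x.mean()


def _check_pair(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    return a, b


def bias(uhat_p, uhat_w) -> StatisticEstimate:
    """mu_wp: mean difference between partial and whole EBV."""
    p, w = _check_pair(uhat_p, uhat_w)
    if len(p) < 1:
        raise ValueError("need at least one focal individual")
    return StatisticEstimate("bias", float(np.mean(p - w)), len(p))


def dispersion(uhat_p, uhat_w) -> StatisticEstimate:
    """b_wp: regression slope of uhat_w on uhat_p (S-quadratic-form ratio)."""
    p, w = _check_pair(uhat_p, uhat_w)
    if len(p) < 3:
        raise ValueError("dispersion needs n >= 3")
    cp = _center(p)
    denom = cp @ cp
    if denom <= 0:
        raise ValueError("degenerate predictor: uhat_p has zero variance")
    return StatisticEstimate("dispersion", float(_center(w) @ cp / denom), len(p))


def ratio_accuracies(uhat_p, uhat_w) -> StatisticEstimate:
    """rho_wp: Pearson correlation of the two EBV sets."""
    p, w = _check_pair(uhat_p, uhat_w)
    if len(p) < 4:
        raise ValueError("ratio of accuracies needs n >= 4")
    cp, cw = _center(p), _center(w)
    vp, vw = cp @ cp, cw @ cw
    if vp <= 0 or vw <= 0:
        raise ValueError("zero variance in EBV")
    return StatisticEstimate(
        "ratio_accuracies", float(cw @ cp / np.sqrt(vp * vw)), len(p)
    )


def reliability_estimate(uhat_p, uhat_w, sigma_gi2: float) -> StatisticEstimate:
    """rho2_cov_wp = uhat_w' S uhat_p / (n sigma_gi2).

    Divisor is ``n`` (not n-1), matching the estimator's definition.  The point
    estimate is deliberately not clamped to [0, 1]: finite samples can leave
    the parameter range.
    """
    p, w = _check_pair(uhat_p, uhat_w)
    n = len(p)
    if n < 2:
        raise ValueError("reliability needs n >= 2")
    if sigma_gi2 <= 0:
        raise ValueError("sigma_gi2 must be positive")
    return StatisticEstimate(
        "reliability", float(_center(w) @ _center(p) / (n * sigma_gi2)), n
    )


def predictivity(ystar, uhat_p, h: float) -> StatisticEstimate:
    """rho_{y*,uhat_p}: corr(adjusted phenotype, partial EBV) / h."""
    ys, p = _check_pair(ystar, uhat_p)
    if len(p) < 4:
        raise ValueError("predictivity needs n >= 4")
    if not 0 < h <= 1:
        raise ValueError("h must lie in (0, 1]")
    cy, cp = _center(ys), _center(p)
    vy, vp = cy @ cy, cp @ cp
    if vy <= 0 or vp <= 0:
        raise ValueError("zero variance in ystar or uhat_p")
    return StatisticEstimate(
        "predictivity", float(cy @ cp / np.sqrt(vy * vp) / h), len(p)
    )


def compute_statistics(inputs, h: float | None = None) -> dict[str, StatisticEstimate]:
    """All five statistics from a :class:`~lrvalidate.blup.ValidationInputs`."""
    if h is None:
        h = inputs.model.h
    return {
        "bias": bias(inputs.uhat_p, inputs.uhat_w),
        "dispersion": dispersion(inputs.uhat_p, inputs.uhat_w),
        "ratio_accuracies": ratio_accuracies(inputs.uhat_p, inputs.uhat_w),
        "reliability": reliability_estimate(inputs.uhat_p, inputs.uhat_w,
                                            inputs.sigma_gi2),
        "predictivity": predictivity(inputs.ystar, inputs.uhat_p, h),
    }
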