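"""Standard errors and confidence intervals for the validation statistics.

Four interval families:

* **analytical** — exact sampling variances from the joint normal distribution
  of (uhat_w, uhat_p), which has Var(uhat_p) = G - C22_p and
  Var(uhat_w - uhat_p) = C22_p - C22_w.  The bias variance is exact; the
  dispersion variance uses a first-order Taylor expansion of the slope ratio
  (the conditional-mean term of the total-variance decomposition is
  identically zero and is never added); the reliability variance follows from
  exact Gaussian quadratic-form moments.
* **approximated** — large-data forms that assume the C-matrices are diagonal,
  so only per-animal reliabilities are needed; a further constant-ratio form
  assumes rel_w/rel_p = c for all animals.
* **fisher** — tanh/atanh transform intervals for the two correlation-type
  statistics (ratio of accuracies and predictivity).
* **bootstrap** — percentile intervals from resampling the focal individuals
  with replacement, keeping each individual's (uhat_p, uhat_w, ystar) tuple
  intact.

The Williams test compares two predictivities that share the same adjusted
phenotypes (dependent correlations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from . import lrstats

__all__ = [
    "IntervalSpec",
    "IntervalResult",
    "ReliabilitySummary",
    "WilliamsResult",
    "reliability_summary",
    "var_bias_analytical",
    "var_bias_approx",
    "var_dispersion_analytical",
    "var_dispersion_approx",
    "var_reliability_analytical",
    "var_reliability_approx",
    "ci_wald",
    "fisher_ci",
    "predictivity_ci",
    "bootstrap_ci",
    "williams_test",
]


@dataclass(frozen=True)
class IntervalSpec:
    """Significance level and the matching standard-normal quantile."""

    alpha: float = 0.05

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def z(self) -> float:
        return float(sps.norm.ppf(1.0 - self.alpha / 2.0))


@dataclass(frozen=True)
class IntervalResult:
    statistic: str
    method: str               # analytical | approximated | fisher | bootstrap
    lower: float
    upper: float
    variance: float | None = None
    metadata: dict = field(default_factory=dict)
    warnings: tuple = ()

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")


@dataclass(frozen=True)
class ReliabilitySummary:
    """Per-animal reliabilities of the focal set and derived scalars.

    ``c`` is the assumed-constant ratio rel_w/rel_p (>= 1: the whole data can
    only add information), computed as mean(rel_w)/mean(rel_p).  ``var_rel_p``
    is the population variance (divisor n), which makes the per-animal and
    constant-c approximations agree exactly for homogeneous reliabilities.
    """

    rel_p: np.ndarray
    rel_w: np.ndarray

    def __post_init__(self):
        rp = np.asarray(self.rel_p, dtype=float)
        rw = np.asarray(self.rel_w, dtype=float)
        if rp.shape != rw.shape or rp.ndim != 1:
            raise ValueError("reliability vectors must be 1-D and equal length")
        if np.any((rp < -1e-12) | (rp > 1 + 1e-12)) or np.any((rw < -1e-12) | (rw > 1 + 1e-12)):
            raise ValueError("reliabilities must lie in [0, 1]")
        object.__setattr__(self, "rel_p", np.clip(rp, 0.0, 1.0))
        object.__setattr__(self, "rel_w", np.clip(rw, 0.0, 1.0))

    @property
    def n(self) -> int:
        return len(self.rel_p)

    @property
    def mean_rel_p(self) -> float:
        return float(self.rel_p.mean())

    @property
    def mean_rel_w(self) -> float:
        return float(self.rel_w.mean())

    @property
    def var_rel_p(self) -> float:
        return float(self.rel_p.var())  # population variance, divisor n

    @property
    def c(self) -> float:
        if self.mean_rel_p <= 0:
            raise ValueError("mean rel_p is zero; constant-c ratio undefined")
        return max(self.mean_rel_w / self.mean_rel_p, 1.0)


def reliability_summary(rel_p, rel_w) -> ReliabilitySummary:
    return ReliabilitySummary(rel_p=np.asarray(rel_p), rel_w=np.asarray(rel_w))


# ---------------------------------------------------------------- helpers

def _double_center(M: np.ndarray) -> np.ndarray:
    """S M S with S = I - 11'/n, via row/column mean subtraction."""
    M = np.asarray(M, dtype=float)
    return M - M.mean(axis=0) - M.mean(axis=1)[:, None] + M.mean()


def _clamp(v: float) -> tuple[float, tuple]:
    if v < 0:
        return 0.0, ("variance clamped to 0 (was negative)",)
    return float(v), ()


# ------------------------------------------------------- analytical variances

def var_bias_analytical(C22_p: np.ndarray, C22_w: np.ndarray, n: int) -> float:
    """Var(mu_wp) = 1'(C22_p - C22_w)1 / n^2 — exact."""
    C22_p = np.asarray(C22_p, dtype=float)
    C22_w = np.asarray(C22_w, dtype=float)
    if C22_p.shape != (n, n) or C22_w.shape != (n, n):
        raise ValueError("C22 blocks must be n x n")
    v, _ = _clamp(float(np.sum(C22_p - C22_w)) / n**2)
    return v


def var_bias_approx(summary: ReliabilitySummary, sigma_g2: float, n: int) -> float:
    """Var(mu_wp) ~ (sigma_g2/n)(mean rel_w - mean rel_p) — diagonal C assumption."""
    v, _ = _clamp(sigma_g2 / n * (summary.mean_rel_w - summary.mean_rel_p))
    return v


def var_dispersion_analytical(G: np.ndarray, C22_p: np.ndarray,
                              C22_w: np.ndarray) -> float:
    """Taylor variance of the slope b_wp.

    tr(S D S P) / (2 tr(S P S P) + tr(S P)^2) with D = C22_p - C22_w and
    P = G - C22_p (the variance of uhat_p).
    """
    P = _double_center(np.asarray(G, float) - np.asarray(C22_p, float))
    D = _double_center(np.asarray(C22_p, float) - np.asarray(C22_w, float))
    num = float(np.sum(D * P.T))                 # tr(D P) on centered blocks
    denom = 2.0 * float(np.sum(P * P.T)) + float(np.trace(P)) ** 2
    if denom <= 0:
        raise ValueError("no variance in uhat_p under the model")
    v, _ = _clamp(num / denom)
    return v


def var_dispersion_approx(summary: ReliabilitySummary, n: int,
                          mode: str = "per_animal") -> float:
    """Reliability-only approximations of Var(b_wp).

    ``per_animal``: sum((rel_w - rel_p) rel_p) / (2 sum(rel_p^2) + sum(rel_p)^2).
    ``constant_c``: (c-1)(V + m^2) / (2(V + m^2) + n m^2), with m = mean(rel_p)
    and V its population variance; needs only rel_p and the scalar c.
    """
    rp, rw = summary.rel_p, summary.rel_w
    if mode == "per_animal":
        denom = 2.0 * float(np.sum(rp**2)) + float(np.sum(rp)) ** 2
        if denom <= 0:
            raise ValueError("all partial reliabilities are zero")
        v, _ = _clamp(float(np.sum((rw - rp) * rp)) / denom)
        return v
    if mode == "constant_c":
        m2 = summary.var_rel_p + summary.mean_rel_p**2
        if m2 <= 0:
            raise ValueError("all partial reliabilities are zero")
        v, _ = _clamp((summary.c - 1.0) * m2 / (2.0 * m2 + n * summary.mean_rel_p**2))
        return v
    raise ValueError("mode must be 'per_animal' or 'constant_c'")


def var_reliability_analytical(G: np.ndarray, C22_p: np.ndarray, C22_w: np.ndarray,
                               n: int, sigma_gi2: float) -> float:
    """Var(rho2_cov_wp) = [tr(S D S P) + 2 tr(S P S P)] / (n sigma_gi2)^2."""
    if sigma_gi2 <= 0:
        raise ValueError("sigma_gi2 must be positive")
    P = _double_center(np.asarray(G, float) - np.asarray(C22_p, float))
    D = _double_center(np.asarray(C22_p, float) - np.asarray(C22_w, float))
    num = float(np.sum(D * P.T)) + 2.0 * float(np.sum(P * P.T))
    v, _ = _clamp(num / (n * sigma_gi2) ** 2)
    return v


def var_reliability_approx(summary: ReliabilitySummary, sigma_g2: float,
                           sigma_gi2: float, n: int) -> float:
    """Var(rho2_cov_wp) ~ (1+c) sigma_g2^2 / (n sigma_gi2^2) * (V + m^2)."""
    if sigma_gi2 <= 0:
        raise ValueError("sigma_gi2 must be positive")
    if summary.mean_rel_p <= 0:
        return 0.0
    m2 = summary.var_rel_p + summary.mean_rel_p**2
    v, _ = _clamp((1.0 + summary.c) * sigma_g2**2 / (n * sigma_gi2**2) * m2)
    return v


# ------------------------------------------------------------------ intervals

def ci_wald(estimate: float, variance: float, spec: IntervalSpec = IntervalSpec(),
            statistic: str = "", method: str = "analytical") -> IntervalResult:
    """estimate +/- z_{1-alpha/2} sqrt(variance)."""
    warn = ()
    if variance < 0:
        variance, warn = 0.0, ("variance clamped to 0 (was negative)",)
    half = spec.z * np.sqrt(variance)
    return IntervalResult(statistic=statistic, method=method,
                          lower=float(estimate - half), upper=float(estimate + half),
                          variance=float(variance),
                          metadata={"alpha": spec.alpha}, warnings=warn)


def fisher_ci(rho: float, n: int, spec: IntervalSpec = IntervalSpec(),
              statistic: str = "ratio_accuracies") -> IntervalResult:
    """tanh(atanh(rho) +/- z / sqrt(n-3)): asymmetric, bounds inside (-1, 1)."""
    if n <= 3:
        raise ValueError("Fisher interval needs n >= 4")
    warn = ()
    if abs(rho) >= 1:
        rho = np.sign(rho) * (1 - 1e-12)
        warn = ("|rho| clamped below 1",)
    half = spec.z / np.sqrt(n - 3)
    zr = np.arctanh(rho)
    return IntervalResult(statistic=statistic, method="fisher",
                          lower=float(np.tanh(zr - half)),
                          upper=float(np.tanh(zr + half)),
                          metadata={"alpha": spec.alpha, "n": n}, warnings=warn)


def predictivity_ci(rho_pred: float, h: float, n: int,
                    spec: IntervalSpec = IntervalSpec()) -> IntervalResult:
    """(1/h) tanh(h atanh(rho_pred) +/- z / sqrt(n-3)).

    The transform scales atanh(rho_pred) by h; bounds live in (-1/h, 1/h).
    Reduces to :func:`fisher_ci` at h = 1.
    """
    if n <= 3:
        raise ValueError("predictivity interval needs n >= 4")
    if not 0 < h <= 1:
        raise ValueError("h must lie in (0, 1]")
    if abs(rho_pred) >= 1:
        raise ValueError("|rho_pred| must be < 1 for the transform")
    half = spec.z / np.sqrt(n - 3)
    zr = h * np.arctanh(rho_pred)
    return IntervalResult(statistic="predictivity", method="fisher",
                          lower=float(np.tanh(zr - half) / h),
                          upper=float(np.tanh(zr + half) / h),
                          metadata={"alpha": spec.alpha, "n": n, "h": h})


# ------------------------------------------------------------------ bootstrap

_BOOT_NEEDS = {
    "bias": ("uhat_p", "uhat_w"),
    "dispersion": ("uhat_p", "uhat_w"),
    "ratio_accuracies": ("uhat_p", "uhat_w"),
    "reliability": ("uhat_p", "uhat_w"),
    "predictivity": ("ystar", "uhat_p"),
}


def _boot_stats(name: str, P: np.ndarray, W: np.ndarray, Y: np.ndarray,
                sigma_gi2: float, h: float) -> np.ndarray:
    """Vectorised statistic over resample rows (B x n matrices)."""
    n = P.shape[1]
    if name == "bias":
        return (P - W).mean(axis=1)
    Pc = P - P.mean(axis=1, keepdims=True)
    if name == "dispersion":
        Wc = W - W.mean(axis=1, keepdims=True)
        return np.sum(Wc * Pc, axis=1) / np.sum(Pc * Pc, axis=1)
    if name == "ratio_accuracies":
        Wc = W - W.mean(axis=1, keepdims=True)
        return np.sum(Wc * Pc, axis=1) / np.sqrt(
            np.sum(Pc * Pc, axis=1) * np.sum(Wc * Wc, axis=1))
    if name == "reliability":
        Wc = W - W.mean(axis=1, keepdims=True)
        return np.sum(Wc * Pc, axis=1) / (n * sigma_gi2)
    if name == "predictivity":
        Yc = Y - Y.mean(axis=1, keepdims=True)
        return np.sum(Yc * Pc, axis=1) / np.sqrt(
            np.sum(Pc * Pc, axis=1) * np.sum(Yc * Yc, axis=1)) / h
    raise ValueError(f"unknown statistic {name!r}")


def bootstrap_ci(inputs, statistic: str, B: int = 10_000,
                 spec: IntervalSpec = IntervalSpec(), seed: int | None = None,
                 kind: str = "percentile") -> IntervalResult:
    """Bootstrap CI by resampling focal individuals with replacement.

    Each individual's tuple (uhat_p, uhat_w, ystar) is kept intact.
    ``kind="percentile"`` (default) uses the alpha/2 and 1-alpha/2 empirical
    quantiles; ``kind="normal"`` uses estimate +/- z * bootstrap SD.  Resamples
    where the statistic is degenerate (zero predictor variance) are redrawn
    and counted.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    if statistic not in _BOOT_NEEDS:
        raise ValueError(f"unknown statistic {statistic!r}")
    uhat_p = np.asarray(inputs.uhat_p, dtype=float)
    uhat_w = np.asarray(inputs.uhat_w, dtype=float)
    ys = getattr(inputs, "ystar", None)
    ystar = np.zeros_like(uhat_p) if ys is None else np.asarray(ys, dtype=float)
    sigma_gi2 = float(getattr(inputs, "sigma_gi2", 1.0))
    h = float(inputs.model.h) if hasattr(inputs, "model") else float(
        getattr(inputs, "h", 1.0))
    n = len(uhat_p)
    rng = np.random.default_rng(seed)

    idx = rng.integers(0, n, size=(B, n))
    P, W, Y = uhat_p[idx], uhat_w[idx], ystar[idx]
    values = _boot_stats(statistic, P, W, Y, sigma_gi2, h)

    redrawn = 0
    bad = ~np.isfinite(values)
    while bad.any():
        redrawn += int(bad.sum())
        idx = rng.integers(0, n, size=(int(bad.sum()), n))
        values[bad] = _boot_stats(statistic, uhat_p[idx], uhat_w[idx],
                                  ystar[idx], sigma_gi2, h)
        newbad = ~np.isfinite(values)
        if newbad.sum() == bad.sum() and redrawn > 50 * B:
            raise ValueError("bootstrap resamples persistently degenerate")
        bad = newbad

    # point estimate on the original sample
    point = _boot_stats(statistic, uhat_p[None, :], uhat_w[None, :],
                        ystar[None, :], sigma_gi2, h)[0]
    sd = float(values.std(ddof=1))
    if kind == "percentile":
        lower = float(np.quantile(values, spec.alpha / 2))
        upper = float(np.quantile(values, 1 - spec.alpha / 2))
    elif kind == "normal":
        lower = float(point - spec.z * sd)
        upper = float(point + spec.z * sd)
    else:
        raise ValueError("kind must be 'percentile' or 'normal'")
    return IntervalResult(
        statistic=statistic, method="bootstrap", lower=lower, upper=upper,
        variance=sd**2,
        metadata={"B": B, "seed": seed, "kind": kind, "alpha": spec.alpha,
                  "redrawn": redrawn, "estimate": float(point)},
    )


# -------------------------------------------------------------- Williams test

@dataclass(frozen=True)
class WilliamsResult:
    rho_A: float
    rho_B: float
    rho_AB: float
    detR: float
    T: float
    df: int
    p_value: float


def williams_test(rho_A: float, rho_B: float, rho_AB: float, n: int) -> WilliamsResult:
    """Williams' t test for two dependent correlations sharing one variable.

    Here: predictivities of two prediction methods A and B against the same
    adjusted phenotypes, with rho_AB the correlation between the two EBV sets.
    |R| = 1 - rho_A^2 - rho_B^2 - rho_AB^2 + 2 rho_A rho_B rho_AB (the
    determinant of the 3x3 correlation matrix).  T ~ t(n-3) approximately.
    """
    if n < 4:
        raise ValueError("Williams test needs n >= 4")
    for r in (rho_A, rho_B):
        if not -1 < r < 1:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if not -1 <= rho_AB <= 1:
        raise ValueError("rho_AB must lie in [-1, 1]")
    if abs(rho_AB) == 1 and rho_A != rho_B:
        raise ValueError("rho_AB = +/-1 with rho_A != rho_B: test undefined")
    if rho_A == rho_B:
        detR = (1 - rho_A**2 - rho_B**2 - rho_AB**2
                + 2 * rho_A * rho_B * rho_AB)
        return WilliamsResult(rho_A=rho_A, rho_B=rho_B, rho_AB=rho_AB,
                              detR=float(detR), T=0.0, df=n - 3, p_value=1.0)
    detR = (1 - rho_A**2 - rho_B**2 - rho_AB**2 + 2 * rho_A * rho_B * rho_AB)
    rbar = (rho_A + rho_B) / 2
    denom = 2 * (n - 1) / (n - 3) * detR + rbar**2 * (1 - rho_AB) ** 3
    if denom <= 0:
        raise ValueError("degenerate correlation structure (denominator <= 0)")
    T = (rho_A - rho_B) * np.sqrt((n - 1) * (1 + rho_AB) / denom)
    df = n - 3
    p = float(2 * sps.t.sf(abs(T), df))
    return WilliamsResult(rho_A=rho_A, rho_B=rho_B, rho_AB=rho_AB,
                          detR=float(detR), T=float(T), df=df, p_value=p)


def williams_from_data(ystar, uhat_p_A, uhat_p_B, h: float = 1.0) -> WilliamsResult:
    """Williams test from raw vectors: predictivity-type correlations of two
    EBV sets against shared adjusted phenotypes (h cancels in the difference of
    raw correlations, so the test is run on the unscaled correlations)."""
    rho_A = lrstats.predictivity(ystar, uhat_p_A, 1.0).value
    rho_B = lrstats.predictivity(ystar, uhat_p_B, 1.0).value
    rho_AB = lrstats.ratio_accuracies(uhat_p_A, uhat_p_B).value
    return williams_test(rho_A, rho_B, rho_AB, len(np.asarray(ystar)))
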