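"""Model/Results front end for validation by data truncation.

Two model classes cover the two data situations:

* :class:`TruncationValidation` — the exact path: pedigree + phenotypes.
  ``fit()`` solves the whole and partial evaluations, extracts exact PEV/PEC
  blocks, and returns a :class:`ValidationResults` with the five statistics,
  analytical / approximated / Fisher / bootstrap intervals and a summary table.
* :class:`TableValidation` — the field path: paired EBV tables plus per-animal
  reliabilities (no PEV machinery), yielding the statistics with approximated,
  Fisher and bootstrap intervals only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import intervals as iv
from . import lrstats
from .blup import (
    Dataset,
    ModelSpec,
    TruncationScheme,
    ValidationInputs,
    run_validation,
)
from .pedigree import Pedigree, RelationshipMatrix

__all__ = ["TruncationValidation", "TableValidation", "ValidationResults"]


class TruncationValidation:
    """Validation of a single-trait animal model by data truncation.

    Parameters
    ----------
    pedigree, data, model
        The pedigree, phenotype records and variance components.
    scheme
        Which animals form the focal (validation) set; defaults to the
        phenotyped animals of the latest pedigree generation.
    sigma_gi2
        Override for the validation-group genetic variance; by default the
        relationship-average formula is used and reported.
    """

    def __init__(self, pedigree: Pedigree, data: Dataset, model: ModelSpec,
                 scheme: TruncationScheme | None = None, *,
                 sigma_gi2: float | None = None, adjust_with: str = "whole",
                 A: RelationshipMatrix | None = None):
        self.pedigree = pedigree
        self.data = data
        self.model = model
        self.scheme = scheme if scheme is not None else TruncationScheme.latest_generation()
        self.sigma_gi2 = sigma_gi2
        self.adjust_with = adjust_with
        self._A = A

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, pedigree: Pedigree, *,
                       h2: float, sigma_g2: float = 1.0,
                       fixed_effects=("mu",), animal_col: str = "animal",
                       trait_col: str = "phenotype", validation_ids=None,
                       **kwargs) -> "TruncationValidation":
        model = ModelSpec.from_h2(h2, sigma_g2=sigma_g2, fixed_effects=fixed_effects)
        data = Dataset(frame=frame, animal_col=animal_col, trait_col=trait_col)
        scheme = (TruncationScheme.explicit(validation_ids)
                  if validation_ids is not None else None)
        return cls(pedigree, data, model, scheme, **kwargs)

    def fit(self, alpha: float = 0.05, *, bootstrap: bool = True,
            bootstrap_B: int = 10_000, bootstrap_kind: str = "percentile",
            seed: int | None = None) -> "ValidationResults":
        spec = iv.IntervalSpec(alpha=alpha)
        inputs = run_validation(self.pedigree, self.data, self.model, self.scheme,
                                sigma_gi2=self.sigma_gi2,
                                adjust_with=self.adjust_with, A=self._A)
        stats = lrstats.compute_statistics(inputs)
        results = _build_intervals(inputs, stats, spec,
                                   bootstrap=bootstrap, bootstrap_B=bootstrap_B,
                                   bootstrap_kind=bootstrap_kind, seed=seed,
                                   exact=True)
        return ValidationResults(model=self, inputs=inputs, estimates=stats,
                                 intervals=results, spec=spec, seed=seed)


class TableValidation:
    """Approximation path: paired EBV and reliability tables, no PEV matrices."""

    def __init__(self, uhat_p, uhat_w, rel_p, rel_w, *, sigma_g2: float,
                 sigma_gi2: float | None = None, ystar=None, h: float | None = None,
                 c_mode: str = "per_animal"):
        self.uhat_p = np.asarray(uhat_p, dtype=float)
        self.uhat_w = np.asarray(uhat_w, dtype=float)
        self.summary_rel = iv.reliability_summary(rel_p, rel_w)
        self.sigma_g2 = float(sigma_g2)
        self.sigma_gi2 = float(sigma_gi2) if sigma_gi2 is not None else float(sigma_g2)
        self.ystar = np.asarray(ystar, dtype=float) if ystar is not None else None
        self.h = h
        self.c_mode = c_mode

    @classmethod
    def from_frames(cls, ebv: pd.DataFrame, rel: pd.DataFrame, *, sigma_g2: float,
                    animal_col: str = "animal", **kwargs) -> "TableValidation":
        """Join an EBV table (animal, ebv_partial, ebv_whole) with a
        reliability table (animal, rel_partial, rel_whole) on animal id."""
        for frame, cols in ((ebv, ("ebv_partial", "ebv_whole")),
                            (rel, ("rel_partial", "rel_whole"))):
            missing = [c for c in (animal_col, *cols) if c not in frame.columns]
            if missing:
                raise ValueError(f"table missing expected columns {missing}")
        merged = ebv.merge(rel, on=animal_col, how="inner", validate="1:1")
        if len(merged) != len(ebv) or len(merged) != len(rel):
            raise ValueError("animal ids do not match between EBV and reliability tables")
        return cls(merged["ebv_partial"], merged["ebv_whole"],
                   merged["rel_partial"], merged["rel_whole"],
                   sigma_g2=sigma_g2, **kwargs)

    def fit(self, alpha: float = 0.05, *, bootstrap: bool = True,
            bootstrap_B: int = 10_000, bootstrap_kind: str = "percentile",
            seed: int | None = None) -> "ValidationResults":
        spec = iv.IntervalSpec(alpha=alpha)
        n = len(self.uhat_p)
        stats = {
            "bias": lrstats.bias(self.uhat_p, self.uhat_w),
            "dispersion": lrstats.dispersion(self.uhat_p, self.uhat_w),
            "ratio_accuracies": lrstats.ratio_accuracies(self.uhat_p, self.uhat_w),
            "reliability": lrstats.reliability_estimate(self.uhat_p, self.uhat_w,
                                                        self.sigma_gi2),
        }
        if self.ystar is not None and self.h is not None:
            stats["predictivity"] = lrstats.predictivity(self.ystar, self.uhat_p,
                                                         self.h)
        inputs = _TableInputs(uhat_p=self.uhat_p, uhat_w=self.uhat_w,
                              ystar=self.ystar, sigma_gi2=self.sigma_gi2,
                              h=self.h or 1.0, n=n)
        results = _build_intervals(inputs, stats, spec, bootstrap=bootstrap,
                                   bootstrap_B=bootstrap_B,
                                   bootstrap_kind=bootstrap_kind, seed=seed,
                                   exact=False, summary_rel=self.summary_rel,
                                   sigma_g2=self.sigma_g2, c_mode=self.c_mode)
        return ValidationResults(model=self, inputs=inputs, estimates=stats,
                                 intervals=results, spec=spec, seed=seed)


@dataclass
class _TableInputs:
    uhat_p: np.ndarray
    uhat_w: np.ndarray
    ystar: np.ndarray | None
    sigma_gi2: float
    h: float
    n: int


def _build_intervals(inputs, stats, spec, *, bootstrap, bootstrap_B,
                     bootstrap_kind, seed, exact, summary_rel=None,
                     sigma_g2=None, c_mode="per_animal") -> list[iv.IntervalResult]:
    out: list[iv.IntervalResult] = []
    n = inputs.n
    if exact:
        summary_rel = iv.reliability_summary(inputs.rel_p, inputs.rel_w)
        sigma_g2 = inputs.model.sigma_g2
        G, Cp, Cw = inputs.G, inputs.C22_p, inputs.C22_w
        out.append(iv.ci_wald(stats["bias"].value, iv.var_bias_analytical(Cp, Cw, n),
                              spec, "bias", "analytical"))
        out.append(iv.ci_wald(stats["dispersion"].value,
                              iv.var_dispersion_analytical(G, Cp, Cw),
                              spec, "dispersion", "analytical"))
        out.append(iv.ci_wald(stats["reliability"].value,
                              iv.var_reliability_analytical(G, Cp, Cw, n,
                                                            inputs.sigma_gi2),
                              spec, "reliability", "analytical"))
    # reliability-only approximations
    out.append(iv.ci_wald(stats["bias"].value,
                          iv.var_bias_approx(summary_rel, sigma_g2, n),
                          spec, "bias", "approximated"))
    mode = "per_animal" if c_mode == "per_animal" else "constant_c"
    out.append(iv.ci_wald(stats["dispersion"].value,
                          iv.var_dispersion_approx(summary_rel, n, mode=mode),
                          spec, "dispersion", "approximated"))
    out.append(iv.ci_wald(stats["reliability"].value,
                          iv.var_reliability_approx(summary_rel, sigma_g2,
                                                    inputs.sigma_gi2, n),
                          spec, "reliability", "approximated"))
    # Fisher-transform intervals for the correlation statistics
    out.append(iv.fisher_ci(stats["ratio_accuracies"].value, n, spec))
    if "predictivity" in stats:
        h = inputs.model.h if exact else inputs.h
        try:
            out.append(iv.predictivity_ci(stats["predictivity"].value, h, n, spec))
        except ValueError as exc:
            warnings.warn(f"no Fisher-type interval for predictivity: {exc}",
                          stacklevel=2)
    if bootstrap:
        for name in stats:
            out.append(iv.bootstrap_ci(inputs, name, B=bootstrap_B, spec=spec,
                                       seed=seed, kind=bootstrap_kind))
    return out


@dataclass
class ValidationResults:
    """Estimates, variances and intervals from a validation fit."""

    model: object
    inputs: object
    estimates: dict
    intervals: list
    spec: iv.IntervalSpec
    seed: int | None = None
    _frame: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.inputs.n

    def conf_int(self, statistic: str, method: str = "analytical") -> tuple[float, float]:
        for r in self.intervals:
            if r.statistic == statistic and r.method == method:
                return (r.lower, r.upper)
        raise KeyError(f"no {method} interval for {statistic}")

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: statistic, method, estimate, variance, lower, upper, ..."""
        if self._frame is not None:
            return self._frame
        rows = []
        for r in self.intervals:
            est = self.estimates[r.statistic].value
            rows.append({
                "statistic": r.statistic, "method": r.method, "estimate": est,
                "variance": r.variance, "lower": r.lower, "upper": r.upper,
                "n": self.n, "alpha": self.spec.alpha,
                "B": r.metadata.get("B"), "seed": r.metadata.get("seed"),
                "warnings": "; ".join(r.warnings),
            })
        self._frame = pd.DataFrame(rows)
        return self._frame

    def summary(self) -> str:
        """Plain-text summary table of estimates and intervals."""
        frame = self.to_frame()
        lines = [
            "Validation by data truncation",
            "=" * 78,
            f"focal individuals: {self.n}    alpha: {self.spec.alpha}"
            + (f"    seed: {self.seed}" if self.seed is not None else ""),
        ]
        meta = getattr(self.inputs, "meta", None)
        if meta:
            lines.append(
                f"sigma_gi2: {self.inputs.sigma_gi2:.6g} ({meta.get('sigma_gi2_mode')})"
                f"    records whole/partial: {meta.get('n_records_whole')}/"
                f"{meta.get('n_records_partial')}"
            )
            if meta.get("near_zero_gain"):
                lines.append("WARNING: C22_p ~ C22_w (near-zero information gain)")
        lines.append("-" * 78)
        lines.append(f"{'statistic':<18}{'method':<14}{'estimate':>10}"
                     f"{'variance':>12}{'lower':>11}{'upper':>11}")
        for _, row in frame.iterrows():
            var = "" if pd.isna(row["variance"]) else f"{row['variance']:.3e}"
            lines.append(
                f"{row['statistic']:<18}{row['method']:<14}{row['estimate']:>10.4f}"
                f"{var:>12}{row['lower']:>11.4f}{row['upper']:>11.4f}")
        lines.append("=" * 78)
        return "\n".join(lines)
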