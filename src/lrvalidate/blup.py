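"""Single-trait animal-model BLUP via Henderson's mixed model equations.

The model is ``y = X b + Z u + e`` with ``u ~ N(0, A sigma_g2)`` and
``e ~ N(0, I sigma_e2)``.  The coefficient matrix is

    [ X'X      X'Z            ]
    [ Z'X      Z'Z + A^-1 λ   ]        λ = sigma_e2 / sigma_g2,

assembled densely over *all* pedigree animals (animals without records enter
through ``A^-1`` and receive parent-average style predictions).  Prediction
error (co)variance blocks ``C22`` are exact: ``sigma_e2`` times the animal
block of the inverse coefficient matrix, obtained from one Cholesky
factorization and targeted solves, never a full inversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .pedigree import (
    Pedigree,
    RelationshipMatrix,
    additive_relationship,
    subset_matrix,
    validation_genetic_variance,
)

__all__ = [
    "ModelSpec",
    "Dataset",
    "TruncationScheme",
    "ValidationInputs",
    "MixedModelEquations",
    "SingularModelError",
    "build_mme",
    "solve_mme",
    "pev_block",
    "truncate_data",
    "run_validation",
]


class SingularModelError(np.linalg.LinAlgError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Variance components and fixed-effect structure of the animal model.

    ``h2 = sigma_g2 / (sigma_g2 + sigma_e2)``; ``h`` is its square root and
    scales the predictivity statistic.
    """

    sigma_g2: float
    sigma_e2: float
    fixed_effects: tuple = ("mu",)

    def __post_init__(self):
        if self.sigma_g2 <= 0 or self.sigma_e2 <= 0:
            raise ValueError("variance components must be positive")
        object.__setattr__(self, "fixed_effects", tuple(self.fixed_effects))

    @classmethod
    def from_h2(cls, h2: float, sigma_g2: float = 1.0,
                fixed_effects: Sequence[str] = ("mu",)) -> "ModelSpec":
        """Fix ``sigma_g2`` and derive ``sigma_e2 = sigma_g2 (1/h2 - 1)``."""
        if not 0 < h2 < 1:
            raise ValueError("h2 must lie in (0, 1)")
        return cls(sigma_g2=sigma_g2, sigma_e2=sigma_g2 * (1.0 / h2 - 1.0),
                   fixed_effects=tuple(fixed_effects))

    @property
    def h2(self) -> float:
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)

    @property
    def h(self) -> float:
        return float(np.sqrt(self.h2))

    @property
    def lam(self) -> float:
        return self.sigma_e2 / self.sigma_g2


@dataclass(frozen=True)
class Dataset:
    """Phenotype records: a DataFrame with animal id, fixed-effect and trait columns."""

    frame: pd.DataFrame
    animal_col: str = "animal"
    trait_col: str = "phenotype"

    def __post_init__(self):
        for col in (self.animal_col, self.trait_col):
            if col not in self.frame.columns:
                raise ValueError(f"dataset missing column {col!r}")

    @property
    def animals(self) -> np.ndarray:
        return self.frame[self.animal_col].to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self.frame[self.trait_col].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)

    def with_phenotypes(self, y: np.ndarray) -> "Dataset":
        """Same records, new phenotype values (used by the simulation harness)."""
        frame = self.frame.copy()
        frame[self.trait_col] = np.asarray(y, dtype=float)
        return replace(self, frame=frame)


@dataclass(frozen=True)
class TruncationScheme:
    """Which animals form the validation (focal) set.

    Either an explicit id list, or a predicate mapping ``(Dataset, Pedigree)``
    to an id list — e.g. :meth:`latest_generation` for the common rule of
    removing the phenotypes of the youngest animals.
    """

    ids: tuple | None = None
    rule: Callable[[Dataset, Pedigree], Sequence] | None = None
    name: str = "explicit"

    @classmethod
    def explicit(cls, ids: Sequence) -> "TruncationScheme":
        return cls(ids=tuple(ids), name="explicit")

    @classmethod
    def latest_generation(cls) -> "TruncationScheme":
        """Phenotyped animals of the most recent pedigree generation."""

        def _rule(data: Dataset, ped: Pedigree):
            if ped.generation is None:
                raise ValueError("pedigree has no generation labels")
            last = ped.generation.max()
            latest = {ped.ids[i] for i in np.flatnonzero(ped.generation == last)}
            return [a for a in data.animals if a in latest]

        return cls(rule=_rule, name="latest_generation")

    def resolve(self, data: Dataset, ped: Pedigree) -> tuple:
        ids = tuple(self.ids) if self.ids is not None else tuple(self.rule(data, ped))
        if not ids:
            raise ValueError("truncation scheme resolved to an empty validation set")
        phenotyped = set(data.animals)
        missing = [a for a in ids if a not in phenotyped]
        if missing:
            raise ValueError(
                f"validation animals without phenotypes in the whole data: {missing[:5]}"
            )
        if len(ids) == len(data):
            raise ValueError("truncation would remove every phenotype record")
        return ids


@dataclass
class MixedModelEquations:
    """Assembled MME with a cached Cholesky factor for repeated solves."""

    coeff: np.ndarray          # (p+q) x (p+q)
    rhs: np.ndarray
    X: np.ndarray              # records x p
    Z: np.ndarray              # records x q (animal incidence)
    fixed_labels: tuple
    animal_ids: tuple
    model: ModelSpec
    _chol: tuple = field(default=None, repr=False)

    @property
    def n_fixed(self) -> int:
        return len(self.fixed_labels)

    def factor(self):
        if self._chol is None:
            try:
                self._chol = cho_factor(self.coeff, lower=True)
            except np.linalg.LinAlgError as exc:
                raise SingularModelError(
                    "MME coefficient matrix is singular; check for confounded "
                    f"fixed-effect levels among {self.fixed_labels}"
                ) from exc
        return self._chol

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        return cho_solve(self.factor(), rhs)


def _design_matrices(ped: Pedigree, data: Dataset, fixed_effects: Sequence[str]):
    """Build X (cell-means for the first factor, drop-first for the rest) and Z."""
    m = len(data)
    cols: list[np.ndarray] = []
    labels: list[str] = []
    effects = [f for f in fixed_effects if f != "mu"]
    if not effects:
        cols.append(np.ones((m, 1)))
        labels.append("mu")
    for k, name in enumerate(effects):
        if name not in data.frame.columns:
            raise ValueError(f"fixed effect column {name!r} missing from data")
        values = data.frame[name]
        levels = sorted(pd.unique(values))
        drop_first = k > 0  # first factor full-rank cell means, rest contrasts
        for lev in (levels[1:] if drop_first else levels):
            cols.append((values == lev).to_numpy(dtype=float)[:, None])
            labels.append(f"{name}={lev}")
    X = np.hstack(cols)
    q = len(ped)
    Z = np.zeros((m, q))
    Z[np.arange(m), ped.positions(data.animals)] = 1.0
    return X, tuple(labels), Z


def build_mme(ped: Pedigree, data: Dataset, model: ModelSpec,
              A: RelationshipMatrix | None = None) -> MixedModelEquations:
    """Assemble Henderson's MME for one dataset.

    ``A`` may be passed in to avoid rebuilding it for whole/partial pairs.
    """
    if A is None:
        A = additive_relationship(ped)
    missing = set(data.animals) - set(ped.ids)
    if missing:
        raise ValueError(f"phenotyped animals absent from pedigree: {sorted(missing)[:5]}")
    X, labels, Z = _design_matrices(ped, data, model.fixed_effects)
    Ainv = np.linalg.inv(A.values)
    Ainv = 0.5 * (Ainv + Ainv.T)
    XtX = X.T @ X
    XtZ = X.T @ Z
    ZtZ = Z.T @ Z
    coeff = np.block([[XtX, XtZ], [XtZ.T, ZtZ + model.lam * Ainv]])
    y = data.y
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    return MixedModelEquations(coeff=coeff, rhs=rhs, X=X, Z=Z,
                               fixed_labels=labels, animal_ids=ped.ids, model=model)


def solve_mme(mme: MixedModelEquations) -> tuple[np.ndarray, np.ndarray]:
    """Direct solve; returns (bhat, uhat) and enforces a 1e-8 relative residual."""
    sol = mme.solve(mme.rhs)
    resid = np.linalg.norm(mme.coeff @ sol - mme.rhs)
    scale = max(np.linalg.norm(mme.rhs), 1.0)
    if resid > 1e-8 * scale:
        raise SingularModelError(f"MME solve residual {resid / scale:.2e} exceeds 1e-8")
    p = mme.n_fixed
    return sol[:p], sol[p:]


def solve_for_phenotypes(mme: MixedModelEquations, data: Dataset,
                         y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Re-solve the factored system for a new phenotype vector (same records)."""
    rhs = np.concatenate([mme.X.T @ y, mme.Z.T @ y])
    sol = mme.solve(rhs)
    p = mme.n_fixed
    return sol[:p], sol[p:]


def pev_block(mme: MixedModelEquations, focal_ids: Sequence) -> np.ndarray:
    """Exact C22 PEV/PEC block for the focal animals.

    ``sigma_e2`` times the (focal, focal) animal block of the inverse
    coefficient matrix, from one unit-vector solve per focal animal.
    """
    index = {a: i for i, a in enumerate(mme.animal_ids)}
    pos = np.array([index[a] for a in focal_ids], dtype=np.intp) + mme.n_fixed
    E = np.zeros((mme.coeff.shape[0], len(pos)))
    E[pos, np.arange(len(pos))] = 1.0
    W = mme.solve(E)
    C22 = mme.model.sigma_e2 * W[pos, :]
    return 0.5 * (C22 + C22.T)


def truncate_data(data: Dataset, scheme: TruncationScheme,
                  ped: Pedigree) -> tuple[Dataset, tuple]:
    """Partial dataset: whole minus the validation animals' phenotypes."""
    focal = scheme.resolve(data, ped)
    focal_set = set(focal)
    keep = ~np.isin(data.animals, list(focal_set))
    partial = replace(data, frame=data.frame.loc[keep].reset_index(drop=True))
    return partial, focal


@dataclass(frozen=True)
class ValidationInputs:
    """Everything the validation statistics and their variances consume.

    All quantities refer to the ``n`` focal (validation) individuals:
    EBV from whole/partial solves, adjusted phenotypes ``ystar``,
    ``G = sigma_g2 * A_vv``, exact PEV/PEC blocks, per-animal reliabilities,
    and the validation-group genetic variance ``sigma_gi2``.
    """

    ids: tuple
    uhat_w: np.ndarray
    uhat_p: np.ndarray
    ystar: np.ndarray
    G: np.ndarray
    C22_w: np.ndarray
    C22_p: np.ndarray
    rel_w: np.ndarray
    rel_p: np.ndarray
    sigma_gi2: float
    model: ModelSpec
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.ids)

    def __post_init__(self):
        n = self.n
        for name in ("uhat_w", "uhat_p", "ystar", "rel_w", "rel_p"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from number of focal ids")
        for name in ("G", "C22_w", "C22_p"):
            m = getattr(self, name)
            if m.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}")
        scale = max(np.trace(self.C22_p) / n, 1e-12)
        gap = np.linalg.eigvalsh(self.C22_p - self.C22_w).min()
        if gap < -1e-8 * max(scale, 1.0):
            raise ValueError(
                "C22_p - C22_w is not PSD: partial data cannot carry more "
                "information than whole data"
            )


def run_validation(ped: Pedigree, data: Dataset, model: ModelSpec,
                   scheme: TruncationScheme, *, sigma_gi2: float | None = None,
                   adjust_with: str = "whole",
                   A: RelationshipMatrix | None = None) -> ValidationInputs:
    """Whole/partial solves plus exact PEV machinery for the focal set.

    ``ystar`` is the focal phenotype minus the fixed-effect fit; by default the
    fixed effects come from the whole-data solve (``adjust_with="partial"``
    uses the partial-data solve where the level is estimable).
    ``sigma_gi2`` defaults to the relationship-average formula
    (:func:`lrvalidate.pedigree.validation_genetic_variance`); pass a value to
    override.
    """
    if A is None:
        A = additive_relationship(ped)
    partial, focal = truncate_data(data, scheme, ped)
    mme_w = build_mme(ped, data, model, A=A)
    mme_p = build_mme(ped, partial, model, A=A)
    bhat_w, uhat_w_all = solve_mme(mme_w)
    bhat_p, uhat_p_all = solve_mme(mme_p)
    pos = ped.positions(focal)
    uhat_w = uhat_w_all[pos]
    uhat_p = uhat_p_all[pos]

    A_vv = subset_matrix(A, focal)
    G = model.sigma_g2 * A_vv.values
    C22_w = pev_block(mme_w, focal)
    C22_p = pev_block(mme_p, focal)
    diag_prior = np.diag(G)
    rel_w = np.clip(1.0 - np.diag(C22_w) / diag_prior, 0.0, 1.0)
    rel_p = np.clip(1.0 - np.diag(C22_p) / diag_prior, 0.0, 1.0)

    if sigma_gi2 is None:
        sigma_gi2_mode = "relationship_average"
        sigma_gi2 = validation_genetic_variance(A_vv, model.sigma_g2)
    else:
        sigma_gi2_mode = "user_supplied"

    # adjusted phenotypes for the focal records
    focal_mask = np.isin(data.animals, list(focal))
    frame_focal = data.frame.loc[focal_mask]
    order = pd.Series(np.arange(len(focal)), index=list(focal))
    perm = order[frame_focal[data.animal_col]].to_numpy()
    if adjust_with == "whole":
        fitted = (mme_w.X @ bhat_w)[focal_mask]
    elif adjust_with == "partial":
        Xf, labels_f, _ = _design_matrices(
            ped, replace(data, frame=frame_focal.reset_index(drop=True)),
            model.fixed_effects)
        bmap = {lab: b for lab, b in zip(mme_p.fixed_labels, bhat_p)}
        missing = [lab for lab in labels_f if lab not in bmap]
        if missing:
            raise ValueError(
                f"fixed-effect levels {missing} not estimable from partial data; "
                "use adjust_with='whole'"
            )
        fitted = Xf @ np.array([bmap[lab] for lab in labels_f])
    else:
        raise ValueError("adjust_with must be 'whole' or 'partial'")
    ystar = np.empty(len(focal))
    ystar[perm] = data.y[focal_mask] - fitted

    near_zero_gain = bool(
        np.trace(C22_p - C22_w) <= 1e-10 * max(np.trace(C22_p), 1.0)
    )
    if near_zero_gain:
        warnings.warn(
            "C22_p ~ C22_w: almost no information gain from partial to whole; "
            "standard errors will be near zero",
            stacklevel=2,
        )
    return ValidationInputs(
        ids=tuple(focal), uhat_w=uhat_w, uhat_p=uhat_p, ystar=ystar, G=G,
        C22_w=C22_w, C22_p=C22_p, rel_w=rel_w, rel_p=rel_p,
        sigma_gi2=float(sigma_gi2), model=model,
        meta={
            "adjust_with": adjust_with,
            "sigma_gi2_mode": sigma_gi2_mode,
            "scheme": scheme.name,
            "near_zero_gain": near_zero_gain,
            "n_records_whole": len(data),
            "n_records_partial": len(partial),
        },
    )
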