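"""Pedigrees and the numerator relationship matrix.

The additive (numerator) relationship matrix ``A`` holds expected additive
relationships between animals implied by the pedigree; ``Var(u) = A * sigma_g2``
for breeding values ``u`` under the infinitesimal model.  The matrix is built
with the tabular method and kept dense: the tool targets desk-scale pedigrees
(up to ~10,000 animals), where direct construction and inversion are exact and
fast enough.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "RelationshipMatrix",
    "PedigreeError",
    "read_pedigree",
    "additive_relationship",
    "subset_matrix",
    "validation_genetic_variance",
]

#: sentinel index for an unknown parent (never a valid row index)
UNKNOWN = -1


class PedigreeError(ValueError):
    """Raised for malformed pedigrees (duplicates, cycles, undeclared parents)."""


@dataclass(frozen=True)
class Pedigree:
    """A topologically sorted pedigree.

    Parameters
    ----------
    ids
        Animal identifiers in processing order (parents before offspring).
    sire, dam
        Integer positions of each animal's parents within ``ids``;
        ``UNKNOWN`` (-1) marks an unknown parent.
    generation
        Optional integer generation label per animal.
    """

    ids: tuple
    sire: np.ndarray
    dam: np.ndarray
    generation: np.ndarray | None = None
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "_index", {a: i for i, a in enumerate(self.ids)})

    def __len__(self) -> int:
        return len(self.ids)

    def position(self, animal) -> int:
        return self._index[animal]

    def positions(self, animals: Sequence) -> np.ndarray:
        try:
            return np.array([self._index[a] for a in animals], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"animal {exc.args[0]!r} not in pedigree") from None

    def founders(self) -> np.ndarray:
        return np.flatnonzero((self.sire == UNKNOWN) & (self.dam == UNKNOWN))


@dataclass(frozen=True)
class RelationshipMatrix:
    """Symmetric PSD matrix of additive relationships for an ordered id set."""

    ids: tuple
    values: np.ndarray

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("relationship matrix shape inconsistent with ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")

    @property
    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients F_i = a_ii - 1."""
        return np.diag(self.values) - 1.0

    def __len__(self) -> int:
        return len(self.ids)


def _normalize_token(tok):
    """Return an int id when the token is integral, else the raw string."""
    try:
        return int(tok)
    except ValueError:
        return tok


def read_pedigree(path) -> Pedigree:
    """Read a 3(+1)-column pedigree file (animal, sire, dam[, generation]).

    Whitespace- or comma-separated; unknown parents coded ``0``; an optional
    header line is auto-detected when the first row is non-numeric.  Rows may
    appear in any order: the result is topologically sorted so that parents
    precede offspring.

    Raises
    ------
    PedigreeError
        On duplicate animal ids, cyclic parentage, or a sire/dam id that never
        appears as an animal row.
    """
    if isinstance(path, (str, Path)):
        text = Path(path).read_text()
    else:  # file-like
        text = path.read()
    if not text.strip():
        raise PedigreeError("empty pedigree file")
    sep = "," if "," in text.splitlines()[0] else r"\s+"
    frame = pd.read_csv(io.StringIO(text), sep=sep, header=None, comment="#",
                        skip_blank_lines=True, dtype=str)
    # header auto-detection: first row non-numeric in every column
    first = frame.iloc[0]
    if all(not str(x).lstrip("-").isdigit() for x in first[:3]):
        frame = frame.iloc[1:].reset_index(drop=True)
    if frame.shape[1] < 3:
        raise PedigreeError("pedigree file needs at least 3 columns (animal sire dam)")
    animals = [_normalize_token(t) for t in frame.iloc[:, 0]]
    sires = [_normalize_token(t) for t in frame.iloc[:, 1]]
    dams = [_normalize_token(t) for t in frame.iloc[:, 2]]
    gen = None
    if frame.shape[1] >= 4 and not frame.iloc[:, 3].isna().any():
        gen = [int(t) for t in frame.iloc[:, 3]]
    return pedigree_from_records(animals, sires, dams, gen)


def pedigree_from_records(animals, sires, dams, generation=None) -> Pedigree:
    """Build a sorted :class:`Pedigree` from parallel id sequences (0 = unknown)."""
    n = len(animals)
    index = {}
    for i, a in enumerate(animals):
        if a == 0:
            raise PedigreeError("animal id 0 is reserved for unknown parents")
        if a in index:
            raise PedigreeError(f"duplicate animal id {a!r}")
        index[a] = i
    for p in list(sires) + list(dams):
        if p != 0 and p not in index:
            raise PedigreeError(f"parent {p!r} never declared as an animal")

    # Kahn topological sort, preserving file order among ready animals.
    parents = [
        tuple(index[p] for p in (sires[i], dams[i]) if p != 0) for i in range(n)
    ]
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = [0] * n
    for i, ps in enumerate(parents):
        indeg[i] = len(ps)
        for p in ps:
            children[p].append(i)
    import heapq

    ready = [i for i in range(n) if indeg[i] == 0]
    heapq.heapify(ready)
    order: list[int] = []
    while ready:
        i = heapq.heappop(ready)
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(ready, c)
    if len(order) != n:
        raise PedigreeError("cyclic parentage detected")

    pos_in_order = {old: new for new, old in enumerate(order)}
    ids = tuple(animals[i] for i in order)
    sire_idx = np.array(
        [pos_in_order[index[sires[i]]] if sires[i] != 0 else UNKNOWN for i in order],
        dtype=np.intp,
    )
    dam_idx = np.array(
        [pos_in_order[index[dams[i]]] if dams[i] != 0 else UNKNOWN for i in order],
        dtype=np.intp,
    )
    gen_arr = None
    if generation is not None:
        gen_arr = np.array([generation[i] for i in order], dtype=int)
    return Pedigree(ids=ids, sire=sire_idx, dam=dam_idx, generation=gen_arr)


def additive_relationship(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Recursion over the sorted pedigree: for animal ``j`` with parents ``s, d``,
    ``a_ij = 0.5 (a_is + a_id)`` for earlier ``i`` and ``a_jj = 1 + 0.5 a_sd``
    (unknown-parent terms are zero).
    """
    n = len(ped)
    A = np.zeros((n, n))
    s, d = ped.sire, ped.dam
    for j in range(n):
        sj, dj = s[j], d[j]
        row = np.zeros(j)
        if sj != UNKNOWN:
            row += 0.5 * A[:j, sj]
        if dj != UNKNOWN:
            row += 0.5 * A[:j, dj]
        A[:j, j] = row
        A[j, :j] = row
        asd = A[sj, dj] if (sj != UNKNOWN and dj != UNKNOWN) else 0.0
        A[j, j] = 1.0 + 0.5 * asd
    return RelationshipMatrix(ids=ped.ids, values=A)


def subset_matrix(A: RelationshipMatrix, ids: Sequence) -> RelationshipMatrix:
    """Principal sub-block of ``A`` in the requested id order."""
    index = {a: i for i, a in enumerate(A.ids)}
    try:
        pos = np.array([index[a] for a in ids], dtype=np.intp)
    except KeyError as exc:
        raise KeyError(f"id {exc.args[0]!r} not in relationship matrix") from None
    return RelationshipMatrix(ids=tuple(ids), values=A.values[np.ix_(pos, pos)])


def validation_genetic_variance(A_vv: RelationshipMatrix | np.ndarray,
                                sigma_g2: float) -> float:
    """Genetic variance of a validation group from average relationships.

    ``sigma_gi2 = sigma_g2 * (mean(diag(A_vv)) - mean(A_vv))`` — the expected
    variance of breeding values within the group, which shrinks when the group
    is closely related (e.g. few large sibships) and vanishes for clones.
    """
    v = A_vv.values if isinstance(A_vv, RelationshipMatrix) else np.asarray(A_vv)
    n = v.shape[0]
    if n < 2:
        raise ValueError("validation group variance undefined for n < 2")
    if sigma_g2 <= 0:
        raise ValueError("sigma_g2 must be positive")
    out = sigma_g2 * (np.mean(np.diag(v)) - np.mean(v))
    return max(out, 0.0)
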