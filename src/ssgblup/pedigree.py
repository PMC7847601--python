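"""Pedigree relationship algebra.

The numerator relationship matrix A (tabular method), its sparse inverse via
Henderson's rules with inbreeding (Meuwissen & Luo), and the genotyped-animal
block A22 with its dense inverse.

Conventions: animals are stored in topological order (parents before
offspring); unknown parents are coded as index -1.  ``diag(A) = 1 + F`` where
F is the inbreeding coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

__all__ = [
    "Pedigree",
    "PedigreeError",
    "build_A",
    "build_A_inverse",
    "build_A22_and_inverse",
]

UNKNOWN = "0"


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, unknown ids)."""


@dataclass
class Pedigree:
    """Topologically ordered animal/sire/dam records.

    Attributes
    ----------
    ids : list of str
        Animal identifiers, parents always before offspring.
    sire, dam : ndarray of int
        Index of each animal's parent within ``ids`` (-1 = unknown).
    year_class : ndarray of object or None
        Optional year-class label per animal.
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    year_class: np.ndarray | None = None
    _index: dict[str, int] = field(init=False, repr=False)
    _inbreeding: np.ndarray | None = field(default=None, init=False, repr=False)

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise PedigreeError("duplicate animal ids in pedigree")
        if self.sire.shape != (n,) or self.dam.shape != (n,):
            raise PedigreeError("sire/dam arrays must match number of animals")
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            bad = (par >= np.arange(n)) & (par != -1)
            if bad.any():
                raise PedigreeError(
                    f"{name} must precede offspring (violated at row {int(np.where(bad)[0][0])})"
                )
        self._index = {a: i for i, a in enumerate(self.ids)}

    # ------------------------------------------------------------------
    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
        *,
        unknown: str = UNKNOWN,
    ) -> "Pedigree":
        """Build a pedigree from (animal, sire, dam[, year_class]) tuples.

        Records may arrive in any order; a topological sort places parents
        first.  Parents that never appear as animals are inserted as founders
        with a warning.  A cycle (an animal that is its own ancestor) raises
        :class:`PedigreeError`.
        """
        rows: dict[str, tuple[str, str]] = {}
        yclass: dict[str, object] = {}
        for rec in records:
            a, s, d = str(rec[0]), str(rec[1]), str(rec[2])
            if a == unknown:
                raise PedigreeError("animal id equals the unknown-parent code")
            if a in rows:
                raise PedigreeError(f"duplicate animal id {a!r}")
            rows[a] = (s, d)
            if len(rec) > 3:
                yclass[a] = rec[3]
        # auto-insert referenced but undefined parents as founders
        inserted = []
        for s, d in list(rows.values()):
            for p in (s, d):
                if p != unknown and p not in rows:
                    rows[p] = (unknown, unknown)
                    inserted.append(p)
        if inserted:
            warnings.warn(
                f"{len(inserted)} parent(s) not listed as animals were inserted "
                f"as founders: {sorted(inserted)[:10]}",
                stacklevel=2,
            )
        # Kahn topological sort, stable on input order
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(a: str, stack: tuple = ()) -> None:
            if state.get(a) == 2:
                return
            if state.get(a) == 1:
                raise PedigreeError(f"pedigree cycle involving animal {a!r}")
            state[a] = 1
            s, d = rows[a]
            for p in (s, d):
                if p != unknown:
                    visit(p, stack + (a,))
            state[a] = 2
            order.append(a)

        for a in rows:
            visit(a)
        index = {a: i for i, a in enumerate(order)}
        sire = np.array(
            [index[rows[a][0]] if rows[a][0] != unknown else -1 for a in order]
        )
        dam = np.array(
            [index[rows[a][1]] if rows[a][1] != unknown else -1 for a in order]
        )
        yc = None
        if yclass:
            yc = np.array([yclass.get(a) for a in order], dtype=object)
        return cls(ids=order, sire=sire, dam=dam, year_class=yc)

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        """Positions of ``ids`` in pedigree order (error on unknown id)."""
        try:
            return np.array([self._index[str(a)] for a in ids], dtype=np.int64)
        except KeyError as exc:
            raise PedigreeError(f"animal {exc.args[0]!r} not in pedigree") from None

    @property
    def founders(self) -> np.ndarray:
        return np.flatnonzero((self.sire == -1) & (self.dam == -1))

    @property
    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients F via the Meuwissen–Luo algorithm."""
        if self._inbreeding is None:
            self._inbreeding = _inbreeding_meuwissen_luo(self.sire, self.dam)
        return self._inbreeding

    def records(self) -> list[tuple[str, str, str]]:
        """(animal, sire, dam) string triples, unknown parent = '0'."""
        out = []
        for i, a in enumerate(self.ids):
            s = self.ids[self.sire[i]] if self.sire[i] >= 0 else UNKNOWN
            d = self.ids[self.dam[i]] if self.dam[i] >= 0 else UNKNOWN
            out.append((a, s, d))
        return out


def _mendelian_d(sire: np.ndarray, dam: np.ndarray, F: np.ndarray, i: int) -> float:
    """Variance of the Mendelian-sampling term for animal i (the D of A=LDL')."""
    s, d = sire[i], dam[i]
    if s >= 0 and d >= 0:
        return 0.5 - 0.25 * (F[s] + F[d])
    if s >= 0 or d >= 0:
        return 0.75 - 0.25 * F[s if s >= 0 else d]
    return 1.0


def _inbreeding_meuwissen_luo(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """F for a topologically ordered pedigree, O(n * ancestors) memory-light.

    For each animal the row of L (from A = LDL') is accumulated over its
    ancestor set; F_i = 0.5 * a(sire, dam) is recovered from
    sum_j L_ij^2 d_j = 0.5 + F_i + 0.25 (F_s + F_d).
    """
    n = len(sire)
    F = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0 or d < 0:
            F[i] = 0.0  # one or both parents unknown -> non-inbred by convention
            continue
        coeff: dict[int, float] = {}
        coeff[s] = coeff.get(s, 0.0) + 0.5
        coeff[d] = coeff.get(d, 0.0) + 0.5
        acc = 0.0
        while coeff:
            j = max(coeff)
            c = coeff.pop(j)
            acc += c * c * _mendelian_d(sire, dam, F, j)
            if sire[j] >= 0:
                coeff[sire[j]] = coeff.get(sire[j], 0.0) + 0.5 * c
            if dam[j] >= 0:
                coeff[dam[j]] = coeff.get(dam[j], 0.0) + 0.5 * c
        F[i] = acc - 0.5 - 0.25 * (F[s] + F[d])
    return F


def build_A(ped: Pedigree) -> np.ndarray:
    """Numerator relationship matrix by the tabular (recursive) method.

    a_ii = 1 + F_i with F_i = 0.5 * a(sire_i, dam_i); off-diagonals follow
    a_ij = 0.5 (a_{j,sire_i} + a_{j,dam_i}) for j < i.
    """
    n = len(ped)
    A = np.zeros((n, n))
    s, d = ped.sire, ped.dam
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            A[i, :i] = 0.5 * (A[si, :i] + A[di, :i])
            A[i, i] = 1.0 + 0.5 * A[si, di]
        elif si >= 0 or di >= 0:
            p = si if si >= 0 else di
            A[i, :i] = 0.5 * A[p, :i]
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0
        A[:i, i] = A[i, :i]
    return A


def build_A_inverse(ped: Pedigree) -> sparse.csr_matrix:
    """Sparse A^-1 by Henderson's rules with inbreeding.

    Uses the Mendelian-sampling variances d_i = 0.5 - 0.25 (F_s + F_d)
    (Meuwissen–Luo F), so the result is the exact inverse of
    :func:`build_A` for inbred pedigrees too.
    """
    n = len(ped)
    F = ped.inbreeding
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i in range(n):
        alpha = 1.0 / _mendelian_d(ped.sire, ped.dam, F, i)
        parents = [p for p in (ped.sire[i], ped.dam[i]) if p >= 0]
        rows.append(i)
        cols.append(i)
        vals.append(alpha)
        for p in parents:
            rows += [i, p]
            cols += [p, i]
            vals += [-0.5 * alpha, -0.5 * alpha]
        for p in parents:
            for q in parents:
                rows.append(p)
                cols.append(q)
                vals.append(0.25 * alpha)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    Ainv.sum_duplicates()
    return Ainv


def build_A22_and_inverse(
    ped: Pedigree, genotyped_ids: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """A restricted to genotyped animals (in the given order) and its inverse.

    The inverse is a dense factorization of the extracted block — never a
    subset of A^-1, which would be wrong whenever genotyped animals have
    non-genotyped relatives.
    """
    idx = ped.index_of(genotyped_ids)
    if len(set(idx.tolist())) != len(idx):
        raise PedigreeError("duplicate ids in genotyped set")
    A = build_A(ped)
    A22 = A[np.ix_(idx, idx)]
    A22_inv = np.linalg.inv(A22)
    # symmetrize against round-off
    A22_inv = 0.5 * (A22_inv + A22_inv.T)
    return A22, A22_inv
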