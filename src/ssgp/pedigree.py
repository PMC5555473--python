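"""Pedigree container and numerator-relationship-matrix algebra.

The numerator relationship matrix A holds pedigree-expected additive
relationships among all individuals.  Single-step analyses never need A
itself at scale: every quantity they use (the J covariate and the imputed
marker covariates of nongenotyped individuals) is a product of the form
``Ang @ inv(Agg) @ V``, which is obtained from the sparse inverse of A via
the partitioned-matrix identity

    Ang Agg^{-1} V = -(A^{nn})^{-1} A^{ng} V,

where A^{nn} and A^{ng} are blocks of A^{-1} indexed by nongenotyped (n)
and genotyped (g) individuals.  :class:`RelationshipOperator` caches a
sparse factorization of A^{nn} so the identity can be applied to many
right-hand sides (one per marker) at the cost of one factorization.

A dense tabular construction of A is also provided for small pedigrees;
it serves as the exact oracle against which the sparse route is tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu

__all__ = [
    "Pedigree",
    "RelationshipOperator",
    "sort_and_validate",
    "inbreeding_coefficients",
    "build_A_tabular",
    "build_A_inverse",
]

UNKNOWN = -1

try:  # inbreeding pass is the one O(n * ancestors) loop; jit when available
    from numba import njit as _njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


class PedigreeError(ValueError):
    """Raised for structural defects: unknown parents, cycles, bad codes."""


@dataclass
class Pedigree:
    """Ordered pedigree over ``n`` individuals.

    Parameters
    ----------
    ids
        Unique individual labels, in storage order.
    sire, dam
        Integer positions of each individual's parents in ``ids``;
        ``-1`` marks an unknown parent.
    generation
        Integer generation label per individual (free-form; the simulator
        uses 0..5 for the selection generations).
    sex
        ``"M"`` or ``"F"`` per individual.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    generation: np.ndarray
    sex: np.ndarray
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.generation = np.asarray(self.generation, dtype=np.int64)
        self.sex = np.asarray(self.sex)
        if not self._index:
            self._index = {v: i for i, v in enumerate(self.ids.tolist())}
        if len(self._index) != self.n:
            raise PedigreeError("duplicate individual ids in pedigree")

    @property
    def n(self) -> int:
        return self.ids.size

    def positions(self, ids) -> np.ndarray:
        """Map an iterable of ids to integer positions (error on misses)."""
        try:
            return np.array([self._index[i] for i in ids], dtype=np.int64)
        except KeyError as e:  # pragma: no cover - message path
            raise PedigreeError(f"id {e.args[0]!r} not in pedigree") from None

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Pedigree":
        """Build from a table with columns id, sire, dam, generation, sex.

        ``0``, empty or NA in sire/dam means unknown.  Records may be in
        any order; they are validated and topologically sorted.
        """
        need = {"id", "sire", "dam", "generation", "sex"}
        missing = need - set(frame.columns)
        if missing:
            raise PedigreeError(f"pedigree table missing columns {sorted(missing)}")
        ids = frame["id"].to_numpy()
        idx = {v: i for i, v in enumerate(ids.tolist())}
        if len(idx) != len(ids):
            raise PedigreeError("duplicate individual ids in pedigree")

        def parent_pos(col):
            out = np.full(len(ids), UNKNOWN, dtype=np.int64)
            for k, v in enumerate(frame[col].tolist()):
                if v is None or (isinstance(v, float) and np.isnan(v)) or v in (0, "0", ""):
                    continue
                if v not in idx:
                    raise PedigreeError(f"{col} id {v!r} of individual {ids[k]!r} not in pedigree")
                out[k] = idx[v]
            return out

        sex = frame["sex"].astype(str).str.upper().str[0].to_numpy()
        if not np.isin(sex, ["M", "F"]).all():
            bad = frame["sex"][~np.isin(sex, ["M", "F"])].iloc[0]
            raise PedigreeError(f"sex code {bad!r} not in {{M, F}}")
        ped = cls(
            ids=ids,
            sire=parent_pos("sire"),
            dam=parent_pos("dam"),
            generation=frame["generation"].to_numpy(),
            sex=sex,
        )
        return sort_and_validate(ped)

    def to_frame(self) -> pd.DataFrame:
        def label(pos):
            return np.where(pos >= 0, self.ids[np.clip(pos, 0, None)], 0)

        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": label(self.sire),
                "dam": label(self.dam),
                "generation": self.generation,
                "sex": self.sex,
            }
        )

    def is_sorted(self) -> bool:
        order = np.arange(self.n)
        return bool(
            ((self.sire < order) | (self.sire == UNKNOWN)).all()
            and ((self.dam < order) | (self.dam == UNKNOWN)).all()
        )


def sort_and_validate(pedigree: Pedigree) -> Pedigree:
    """Topologically order a pedigree so parents precede offspring.

    Kahn's algorithm on the parent->offspring DAG.  A cycle (an individual
    that is its own ancestor) is a hard error naming one individual on it.
    """
    n = pedigree.n
    for i in range(n):
        if pedigree.sire[i] == i or pedigree.dam[i] == i:
            raise PedigreeError(f"individual {pedigree.ids[i]!r} is its own parent")
    if pedigree.is_sorted():
        return pedigree

    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for p in (pedigree.sire[i], pedigree.dam[i]):
            if p != UNKNOWN:
                children[p].append(i)
                indeg[i] += 1
    order = []
    ready = [i for i in range(n) if indeg[i] == 0]
    while ready:
        i = ready.pop()
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                ready.append(c)
    if len(order) < n:
        stuck = int(np.flatnonzero(indeg > 0)[0])
        raise PedigreeError(
            f"pedigree cycle detected involving individual {pedigree.ids[stuck]!r}"
        )
    order = np.array(order, dtype=np.int64)
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)

    new_sire = np.full(n, UNKNOWN, dtype=np.int64)
    new_dam = np.full(n, UNKNOWN, dtype=np.int64)
    for new_i, old_i in enumerate(order):
        s, d = pedigree.sire[old_i], pedigree.dam[old_i]
        new_sire[new_i] = rank[s] if s != UNKNOWN else UNKNOWN
        new_dam[new_i] = rank[d] if d != UNKNOWN else UNKNOWN
    return Pedigree(
        ids=pedigree.ids[order],
        sire=new_sire,
        dam=new_dam,
        generation=pedigree.generation[order],
        sex=pedigree.sex[order],
    )


def _inbreeding_kernel(sire, dam):
    """Meuwissen & Luo-style inbreeding pass over a sorted pedigree.

    For each individual the ancestor set is gathered, then processed
    youngest-first accumulating path coefficients L; the diagonal of A is
    sum(L_j^2 * D_j) over ancestors j with Mendelian-sampling variance D_j.
    """
    n = sire.size
    F = np.zeros(n)
    L = np.zeros(n)
    visited = np.full(n, -1, dtype=np.int64)
    stack = np.empty(n, dtype=np.int64)
    anc = np.empty(n, dtype=np.int64)
    for i in range(n):
        s = sire[i]
        d = dam[i]
        if s < 0 or d < 0:
            continue  # unknown parent treated as unrelated founder: F = 0
        if i > 0 and s == sire[i - 1] and d == dam[i - 1]:
            F[i] = F[i - 1]  # full sibs share F
            continue
        top = 0
        na = 0
        stack[top] = i
        top += 1
        visited[i] = i
        while top > 0:
            top -= 1
            j = stack[top]
            anc[na] = j
            na += 1
            for p in (sire[j], dam[j]):
                if p >= 0 and visited[p] != i:
                    visited[p] = i
                    stack[top] = p
                    top += 1
        order = np.sort(anc[:na])[::-1]
        L[i] = 1.0
        acc = -1.0
        for k in range(na):
            j = order[k]
            sj = sire[j]
            dj = dam[j]
            lj = L[j]
            if sj >= 0:
                L[sj] += 0.5 * lj
            if dj >= 0:
                L[dj] += 0.5 * lj
            if sj >= 0 and dj >= 0:
                Dj = 0.5 - 0.25 * (F[sj] + F[dj])
            elif sj >= 0:
                Dj = 0.75 - 0.25 * F[sj]
            elif dj >= 0:
                Dj = 0.75 - 0.25 * F[dj]
            else:
                Dj = 1.0
            acc += lj * lj * Dj
            L[j] = 0.0
        F[i] = acc
    return F


if _HAVE_NUMBA:
    _inbreeding_fast = _njit(cache=False)(_inbreeding_kernel)
else:  # pragma: no cover
    _inbreeding_fast = _inbreeding_kernel


def inbreeding_coefficients(pedigree: Pedigree) -> np.ndarray:
    """Inbreeding coefficient F per individual (sorted pedigree required)."""
    if not pedigree.is_sorted():
        pedigree = sort_and_validate(pedigree)
    return _inbreeding_fast(pedigree.sire, pedigree.dam)


def mendelian_variances(pedigree: Pedigree, F: np.ndarray | None = None) -> np.ndarray:
    """Mendelian-sampling variance d_i (share of A's diagonal not explained
    by the parent average), accounting for parental inbreeding."""
    if F is None:
        F = inbreeding_coefficients(pedigree)
    s, d = pedigree.sire, pedigree.dam
    Fs = np.where(s >= 0, F[np.clip(s, 0, None)], 0.0)
    Fd = np.where(d >= 0, F[np.clip(d, 0, None)], 0.0)
    both = (s >= 0) & (d >= 0)
    one = (s >= 0) ^ (d >= 0)
    out = np.ones(pedigree.n)
    out[both] = 0.5 - 0.25 * (Fs[both] + Fd[both])
    out[one] = 0.75 - 0.25 * (Fs[one] + Fd[one])
    if (out <= 0).any():
        bad = pedigree.ids[int(np.flatnonzero(out <= 0)[0])]
        raise PedigreeError(
            f"non-positive Mendelian-sampling variance at {bad!r}: corrupt pedigree"
        )
    return out


def build_A_tabular(pedigree: Pedigree) -> np.ndarray:
    """Dense A by the recursive tabular method (small-pedigree oracle).

    a_ii = 1 + F_i with F_i half the additive relationship of the parents;
    a_ij for j < i is the parent-average recursion.
    """
    if not pedigree.is_sorted():
        pedigree = sort_and_validate(pedigree)
    n = pedigree.n
    A = np.zeros((n, n))
    s, d = pedigree.sire, pedigree.dam
    for i in range(n):
        asd = A[s[i], d[i]] if (s[i] >= 0 and d[i] >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
        for j in range(i):
            a = 0.0
            if s[i] >= 0:
                a += 0.5 * A[j, s[i]]
            if d[i] >= 0:
                a += 0.5 * A[j, d[i]]
            A[i, j] = A[j, i] = a
    return A


def build_A_inverse(pedigree: Pedigree) -> sparse.csc_matrix:
    """Sparse A^{-1} by Henderson's rules with inbreeding.

    Per individual i with Mendelian variance d_i and b = 1/d_i the
    contributions are b at (i,i), -b/2 at (i,parent), and b/4 among known
    parents.  At most 9 entries per individual, so A^{-1} stays sparse for
    pedigrees of any depth.
    """
    if not pedigree.is_sorted():
        pedigree = sort_and_validate(pedigree)
    n = pedigree.n
    dvar = mendelian_variances(pedigree)
    b = 1.0 / dvar
    rows, cols, vals = [], [], []

    idx = np.arange(n)
    rows.append(idx)
    cols.append(idx)
    vals.append(b)
    for parent in (pedigree.sire, pedigree.dam):
        known = parent >= 0
        rows.append(idx[known])
        cols.append(parent[known])
        vals.append(-0.5 * b[known])
        rows.append(parent[known])
        cols.append(idx[known])
        vals.append(-0.5 * b[known])
        rows.append(parent[known])
        cols.append(parent[known])
        vals.append(0.25 * b[known])
    both = (pedigree.sire >= 0) & (pedigree.dam >= 0)
    for r, c in ((pedigree.sire, pedigree.dam), (pedigree.dam, pedigree.sire)):
        rows.append(r[both])
        cols.append(c[both])
        vals.append(0.25 * b[both])
    A_inv = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsc()
    A_inv.sum_duplicates()
    return A_inv


class RelationshipOperator:
    """Applies Ang Agg^{-1} to arbitrary genotyped-indexed columns.

    Built once per (pedigree, genotyped set); the sparse LU factorization
    of the nn-block of A^{-1} is cached and reused for the J covariate and
    for every marker column imputed.
    """

    def __init__(self, pedigree: Pedigree, genotyped_ids):
        if not pedigree.is_sorted():
            pedigree = sort_and_validate(pedigree)
        self.pedigree = pedigree
        gpos = pedigree.positions(genotyped_ids)
        if np.unique(gpos).size != gpos.size:
            raise PedigreeError("duplicate ids in genotyped set")
        mask = np.zeros(pedigree.n, dtype=bool)
        mask[gpos] = True
        self.genotyped_ids = np.asarray(list(genotyped_ids))
        self.nongenotyped_ids = pedigree.ids[~mask]
        self._gpos = gpos
        self._npos = np.flatnonzero(~mask)
        self.A_inv = build_A_inverse(pedigree)
        self.A_inv_nn = self.A_inv[self._npos][:, self._npos].tocsc()
        self._A_inv_ng = self.A_inv[self._npos][:, self._gpos].tocsc()
        if self._npos.size:
            try:
                self._nn_factor = splu(self.A_inv_nn)
            except RuntimeError as e:  # pragma: no cover
                raise PedigreeError(f"singular nongenotyped block: {e}") from None
        else:
            self._nn_factor = None

    @property
    def n_genotyped(self) -> int:
        return self._gpos.size

    @property
    def n_nongenotyped(self) -> int:
        return self._npos.size

    def solve_nn_block(self, V: np.ndarray) -> np.ndarray:
        """Return Ang Agg^{-1} V for V with one row per genotyped individual.

        Computed as -(A^{nn})^{-1} (A^{ng} V); neither Agg nor Ang is formed.
        """
        V = np.atleast_2d(np.asarray(V, dtype=float))
        if V.shape[0] != self._gpos.size:
            if V.T.shape[0] == self._gpos.size and V.shape[0] == 1:
                V = V.T
            else:
                raise ValueError(
                    f"rhs has {V.shape[0]} rows, expected {self._gpos.size} genotyped rows"
                )
        if self._npos.size == 0:
            return np.zeros((0, V.shape[1]))
        rhs = self._A_inv_ng @ V
        return -self._nn_factor.solve(rhs)

    def solve_nn_system(self, rhs: np.ndarray) -> np.ndarray:
        """Solve A^{nn} x = rhs (rows indexed by nongenotyped individuals)."""
        rhs = np.asarray(rhs, dtype=float)
        if self._npos.size == 0:
            return np.zeros_like(rhs)
        return self._nn_factor.solve(rhs)
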