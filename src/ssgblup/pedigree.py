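"""Pedigree parsing and numerator-relationship-matrix machinery.

Builds the additive (numerator) relationship matrix A by the tabular
method, its sparse inverse by Henderson's rules with inbreeding
(Mendelian-sampling variances from a Meuwissen & Luo style inbreeding
evaluation), and the genotyped-animal block A22.

Animal identifiers are opaque strings; internally every routine works on
a contiguous, topologically sorted ordering in which parents precede
offspring. Unknown parents are treated as unrelated, non-inbred
founders (no genetic groups).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

#: sentinel index for an unknown parent
UNKNOWN = -1


@dataclass
class Pedigree:
    """A topologically sorted pedigree.

    ``sire[i]``/``dam[i]`` are positions of animal *i*'s parents in
    ``ids`` (or :data:`UNKNOWN`); every known parent precedes its
    offspring.
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    generation: np.ndarray
    index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {a: i for i, a in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def positions(self, ids: list[str]) -> np.ndarray:
        missing = [a for a in ids if a not in self.index]
        if missing:
            raise KeyError(f"ids not in pedigree: {missing[:10]}"
                           + (" ..." if len(missing) > 10 else ""))
        return np.asarray([self.index[a] for a in ids], dtype=np.int64)

    def ancestors_of(self, positions: np.ndarray) -> np.ndarray:
        """Positions of the given animals plus all their ancestors, sorted."""
        keep = np.zeros(self.n, dtype=bool)
        stack = list(np.asarray(positions, dtype=np.int64))
        while stack:
            i = stack.pop()
            if keep[i]:
                continue
            keep[i] = True
            for p in (self.sire[i], self.dam[i]):
                if p != UNKNOWN and not keep[p]:
                    stack.append(p)
        return np.flatnonzero(keep)

    def subset(self, positions: np.ndarray) -> "Pedigree":
        """Restrict to the given (sorted) positions; parents outside become unknown."""
        positions = np.asarray(positions, dtype=np.int64)
        remap = {int(p): k for k, p in enumerate(positions)}

        def rm(p: int) -> int:
            return remap.get(int(p), UNKNOWN)

        return Pedigree(
            ids=[self.ids[p] for p in positions],
            sire=np.asarray([rm(self.sire[p]) for p in positions], dtype=np.int64),
            dam=np.asarray([rm(self.dam[p]) for p in positions], dtype=np.int64),
            generation=self.generation[positions].copy(),
        )

    @classmethod
    def from_records(
        cls, records: list[tuple[str, str | None, str | None]],
        unknown_code: str = "0",
    ) -> "Pedigree":
        """Build from (animal, sire, dam) triples.

        Parents that never appear as animals are inserted as founders.
        Raises on duplicate ids and on cycles (mutual ancestry).
        """
        seen: dict[str, tuple[str | None, str | None]] = {}
        for a, s, d in records:
            a = str(a)
            if a in seen:
                raise ValueError(f"duplicate animal id: {a!r}")
            norm = lambda p: None if p is None or str(p) == unknown_code or str(p) == "" else str(p)
            seen[a] = (norm(s), norm(d))
        # implicit founders
        for s, d in list(seen.values()):
            for p in (s, d):
                if p is not None and p not in seen:
                    seen[p] = (None, None)

        # Kahn topological sort, parents before offspring
        ids = list(seen)
        pos = {a: i for i, a in enumerate(ids)}
        n = len(ids)
        indeg = np.zeros(n, dtype=np.int64)
        children: list[list[int]] = [[] for _ in range(n)]
        for a, (s, d) in seen.items():
            for p in (s, d):
                if p is not None:
                    children[pos[p]].append(pos[a])
                    indeg[pos[a]] += 1
        order: list[int] = []
        queue = [i for i in range(n) if indeg[i] == 0]
        gen = np.zeros(n, dtype=np.int64)
        while queue:
            i = queue.pop()
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                gen[c] = max(gen[c], gen[i] + 1)
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != n:
            on_cycle = ids[int(np.flatnonzero(indeg > 0)[0])]
            raise ValueError(f"pedigree contains a cycle involving animal {on_cycle!r}")

        sorted_ids = [ids[i] for i in order]
        new_pos = {a: i for i, a in enumerate(sorted_ids)}
        sire = np.full(n, UNKNOWN, dtype=np.int64)
        dam = np.full(n, UNKNOWN, dtype=np.int64)
        for a, (s, d) in seen.items():
            i = new_pos[a]
            if s is not None:
                sire[i] = new_pos[s]
            if d is not None:
                dam[i] = new_pos[d]
        return cls(ids=sorted_ids, sire=sire, dam=dam,
                   generation=np.asarray([gen[pos[a]] for a in sorted_ids]))


@dataclass
class RelationshipMatrixA:
    """Dense additive relationship matrix over an ordered animal list."""

    ids: list[str]
    values: np.ndarray
    inbreeding: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class SparseAInverse:
    """Sparse inverse of A over the full pedigree ordering."""

    ids: list[str]
    matrix: sparse.csr_matrix
    inbreeding: np.ndarray
    mendelian_variance: np.ndarray

    def write_triplets_tsv(self, path) -> None:
        coo = self.matrix.tocoo()
        pd.DataFrame({
            "id_i": [self.ids[i] for i in coo.row],
            "id_j": [self.ids[j] for j in coo.col],
            "value": coo.data,
        }).to_csv(path, sep="\t", index=False)


def read_pedigree(path, unknown_code: str = "0") -> Pedigree:
    """Read a CSV with columns animal,sire,dam (extra columns ignored)."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 3:
        raise ValueError("pedigree CSV needs at least 3 columns (animal, sire, dam)")
    recs = list(df.iloc[:, :3].itertuples(index=False, name=None))
    return Pedigree.from_records(recs, unknown_code=unknown_code)


def write_pedigree(ped: Pedigree, path) -> None:
    pd.DataFrame({
        "animal": ped.ids,
        "sire": ["0" if s == UNKNOWN else ped.ids[s] for s in ped.sire],
        "dam": ["0" if d == UNKNOWN else ped.ids[d] for d in ped.dam],
    }).to_csv(path, index=False)


def _tabular_A(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Dense A by the tabular method (pedigree must be sorted)."""
    n = len(sire)
    A = np.zeros((n, n))
    for j in range(n):
        s, d = sire[j], dam[j]
        if j > 0:
            row = np.zeros(j)
            if s != UNKNOWN:
                row += A[s, :j]
            if d != UNKNOWN:
                row += A[d, :j]
            row *= 0.5
            A[j, :j] = row
            A[:j, j] = row
        asd = A[s, d] if (s != UNKNOWN and d != UNKNOWN) else 0.0
        A[j, j] = 1.0 + 0.5 * asd
    return A


def compute_A(ped: Pedigree, subset: list[str] | None = None) -> RelationshipMatrixA:
    """Additive relationship matrix, optionally restricted to ``subset``.

    With a subset, the pedigree is first pruned to the subset plus all
    of its ancestors (values are identical to slicing the full-pedigree
    A), and the result is returned in the order of ``subset``.
    """
    if subset is None:
        A = _tabular_A(ped.sire, ped.dam)
        return RelationshipMatrixA(list(ped.ids), A, np.diag(A) - 1.0)
    want = ped.positions(list(subset))
    anc = ped.ancestors_of(want)
    sub = ped.subset(anc)
    A_full = _tabular_A(sub.sire, sub.dam)
    sel = sub.positions(list(subset))
    A = A_full[np.ix_(sel, sel)]
    return RelationshipMatrixA(list(subset), A, np.diag(A) - 1.0)


def inbreeding(ped: Pedigree) -> tuple[np.ndarray, np.ndarray]:
    """Inbreeding coefficients F and Mendelian-sampling variances d.

    Meuwissen & Luo style: for each animal, a_ii = sum over ancestors of
    L^2 * d, traversed through the sorted pedigree. d uses the
    convention F(unknown parent) = -1, giving d = 1 (no parents known),
    0.75 (one known), 0.5 - 0.25(F_s + F_d) (both known).
    """
    n = ped.n
    sire, dam = ped.sire, ped.dam
    F = np.zeros(n)
    d = np.zeros(n)
    for i in range(n):
        s, t = sire[i], dam[i]
        Fs = F[s] if s != UNKNOWN else -1.0
        Fd = F[t] if t != UNKNOWN else -1.0
        d[i] = 0.5 - 0.25 * (Fs + Fd)
        if s == UNKNOWN or t == UNKNOWN:
            F[i] = 0.0
            continue
        # trace ancestors of i, accumulating path coefficients L
        L: dict[int, float] = {i: 1.0}
        aii = 0.0
        for j in range(i, -1, -1):
            lj = L.pop(j, 0.0)
            if lj == 0.0:
                continue
            aii += lj * lj * d[j]
            half = 0.5 * lj
            for p in (sire[j], dam[j]):
                if p != UNKNOWN:
                    L[p] = L.get(p, 0.0) + half
        F[i] = aii - 1.0
    return F, d


def compute_A_inverse(ped: Pedigree) -> SparseAInverse:
    """Sparse A^-1 by Henderson's rules, accounting for inbreeding."""
    F, d = inbreeding(ped)
    n = ped.n
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    inv_d = 1.0 / d
    idx = np.arange(n)
    add(idx, idx, inv_d)
    for i in range(n):
        s, t = ped.sire[i], ped.dam[i]
        w = inv_d[i]
        for p in (s, t):
            if p != UNKNOWN:
                add(np.array([i, p]), np.array([p, i]), np.array([-0.5 * w] * 2))
                add(np.array([p]), np.array([p]), np.array([0.25 * w]))
        if s != UNKNOWN and t != UNKNOWN and s != t:
            add(np.array([s, t]), np.array([t, s]), np.array([0.25 * w] * 2))
    mat = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    return SparseAInverse(list(ped.ids), mat, F, d)


def extract_A22(ped: Pedigree, genotyped_ids: list[str]) -> RelationshipMatrixA:
    """A restricted to the genotyped animals, in the stated order."""
    return compute_A(ped, subset=list(genotyped_ids))
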