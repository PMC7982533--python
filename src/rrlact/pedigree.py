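"""Pedigree handling and the additive (numerator) relationship matrix.

The animal model needs the pedigree twice: densely, as the relationship
matrix A whose entry A_ij is twice the kinship between animals i and j, and
sparsely, as A^-1 assembled directly from parentage by Henderson's rules with
inbreeding coefficients from the Meuwissen & Luo algorithm.  Unknown parents
are treated as unrelated, non-inbred founders (no genetic groups).
"""

from __future__ import annotations

from dataclasses import dataclass
from graphlib import CycleError, TopologicalSorter

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = ["Pedigree", "validate_and_sort", "relationship_matrix", "a_inverse", "read_pedigree_csv"]

UNKNOWN = 0  # sentinel for an unknown parent in integer-coded pedigrees


@dataclass
class Pedigree:
    """Topologically ordered pedigree.

    ``sire_idx``/``dam_idx`` hold 0-based positions of each animal's parents in
    ``animals``, or -1 for unknown.  Parents always precede offspring.
    """

    animals: list
    sire_idx: np.ndarray
    dam_idx: np.ndarray

    def __post_init__(self) -> None:
        self.sire_idx = np.asarray(self.sire_idx, dtype=np.int64)
        self.dam_idx = np.asarray(self.dam_idx, dtype=np.int64)
        n = len(self.animals)
        if self.sire_idx.shape != (n,) or self.dam_idx.shape != (n,):
            raise ValueError("parent index arrays must match the animal list length")
        for name, idx in (("sire", self.sire_idx), ("dam", self.dam_idx)):
            if np.any(idx >= np.arange(n)):
                bad = int(np.argmax(idx >= np.arange(n)))
                raise ValueError(
                    f"pedigree not sorted: {name} of animal {self.animals[bad]!r} "
                    "does not precede it"
                )
        self._index = {a: i for i, a in enumerate(self.animals)}
        self._inbreeding: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.animals)

    def index_of(self, animal) -> int:
        try:
            return self._index[animal]
        except KeyError:
            raise KeyError(f"animal {animal!r} not in pedigree") from None

    @property
    def n_founders(self) -> int:
        return int(np.sum((self.sire_idx < 0) & (self.dam_idx < 0)))

    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients by the Meuwissen & Luo algorithm (cached)."""
        if self._inbreeding is None:
            self._inbreeding = _meuwissen_luo_inbreeding(self.sire_idx, self.dam_idx)
        return self._inbreeding

    def log_det_a(self) -> float:
        """log |A| from the L D L' decomposition implied by the pedigree."""
        _, d = _mendelian_variances(self.sire_idx, self.dam_idx, self.inbreeding())
        return float(np.sum(np.log(d)))

    def to_frame(self) -> pd.DataFrame:
        sire = [self.animals[i] if i >= 0 else UNKNOWN for i in self.sire_idx]
        dam = [self.animals[i] if i >= 0 else UNKNOWN for i in self.dam_idx]
        return pd.DataFrame({"animal": self.animals, "sire": sire, "dam": dam})


def validate_and_sort(raw_triples) -> Pedigree:
    """Build a topologically ordered :class:`Pedigree` from (animal, sire, dam) triples.

    Parents referenced but never listed as animals are added as founders.
    ``0``, ``None``, ``NaN`` and ``""`` all encode an unknown parent.
    Raises on duplicate animal ids and on parentage cycles (naming the cycle).
    """
    triples = [(a, _norm_parent(s), _norm_parent(d)) for a, s, d in raw_triples]
    seen = set()
    for a, _, _ in triples:
        if a in seen:
            raise ValueError(f"duplicate animal id {a!r} in pedigree")
        if a is None:
            raise ValueError("animal id may not be missing")
        seen.add(a)

    parents = {a: (s, d) for a, s, d in triples}
    # implicit founders: parents that never appear as animals
    for _, s, d in triples:
        for p in (s, d):
            if p is not None and p not in parents:
                parents[p] = (None, None)

    graph = {a: [p for p in ps if p is not None] for a, ps in parents.items()}
    try:
        order = list(TopologicalSorter(graph).static_order())
    except CycleError as exc:
        raise ValueError(f"pedigree contains a parentage cycle: {exc.args[1]}") from exc

    pos = {a: i for i, a in enumerate(order)}
    sire_idx = np.array([pos[parents[a][0]] if parents[a][0] is not None else -1 for a in order])
    dam_idx = np.array([pos[parents[a][1]] if parents[a][1] is not None else -1 for a in order])
    return Pedigree(order, sire_idx, dam_idx)


def _norm_parent(p):
    if p is None:
        return None
    if isinstance(p, float) and np.isnan(p):
        return None
    if p == 0 or p == "0" or p == "":
        return None
    return p


def relationship_matrix(ped: Pedigree, dense_limit: int = 5000) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular method.

    A_ii = 1 + F_i with F_i = A_{sire,dam}/2; A_ij = (A_{j,sire(i)} + A_{j,dam(i)})/2.
    """
    n = len(ped)
    if n > dense_limit:
        raise ValueError(f"pedigree of {n} animals exceeds dense limit {dense_limit}")
    A = np.zeros((n, n))
    s, d = ped.sire_idx, ped.dam_idx
    for i in range(n):
        diag = 1.0
        if s[i] >= 0 and d[i] >= 0:
            diag += 0.5 * A[s[i], d[i]]
        A[i, i] = diag
        row = np.zeros(n)
        if s[i] >= 0:
            row += 0.5 * A[s[i], :]
        if d[i] >= 0:
            row += 0.5 * A[d[i], :]
        A[i, :i] = row[:i]
        A[:i, i] = row[:i]
    return A


def _meuwissen_luo_inbreeding(sire_idx: np.ndarray, dam_idx: np.ndarray) -> np.ndarray:
    """Inbreeding coefficients without forming A (Meuwissen & Luo recursion).

    For each animal the algorithm walks its ancestor list accumulating
    L-column contributions weighted by within-family (Mendelian-sampling)
    variances d.
    """
    n = sire_idx.shape[0]
    F = np.zeros(n)
    d = np.zeros(n)
    for i in range(n):
        si, di = sire_idx[i], dam_idx[i]
        Fs = F[si] if si >= 0 else -1.0  # -1 encodes "unknown parent" in d formula
        Fd = F[di] if di >= 0 else -1.0
        d[i] = 0.5 - 0.25 * (Fs + Fd)
        if si < 0 or di < 0:
            F[i] = 0.0
            continue
        # accumulate L entries over the union of ancestors of i
        L = {i: 1.0}
        stack = [i]
        # process ancestors in decreasing index order
        order = []
        visited = {i}
        while stack:
            j = stack.pop()
            order.append(j)
            for p in (sire_idx[j], dam_idx[j]):
                if p >= 0 and p not in visited:
                    visited.add(p)
                    stack.append(p)
        order.sort(reverse=True)
        f = 0.0
        for j in order:
            lj = L.get(j, 0.0)
            if lj == 0.0:
                continue
            for p in (sire_idx[j], dam_idx[j]):
                if p >= 0:
                    L[p] = L.get(p, 0.0) + 0.5 * lj
            f += lj * lj * d[j]
        F[i] = f - 1.0
    return F


def _mendelian_variances(sire_idx, dam_idx, F) -> tuple[np.ndarray, np.ndarray]:
    """Within-family variances d_i of the A = T D T' decomposition."""
    n = sire_idx.shape[0]
    d = np.empty(n)
    for i in range(n):
        si, di = sire_idx[i], dam_idx[i]
        if si >= 0 and di >= 0:
            d[i] = 0.5 - 0.25 * (F[si] + F[di])
        elif si >= 0 or di >= 0:
            p = si if si >= 0 else di
            d[i] = 0.75 - 0.25 * F[p]
        else:
            d[i] = 1.0
    return F, d


def a_inverse(ped: Pedigree, inbreeding: bool = True) -> sparse.csr_matrix:
    """Sparse A^-1 by Henderson's rules.

    With ``inbreeding=True`` (default) the within-family variances use
    Meuwissen-Luo inbreeding coefficients; ``False`` gives Henderson's
    non-inbred shortcut (useful only as a cross-check).
    """
    n = len(ped)
    F = ped.inbreeding() if inbreeding else np.zeros(n)
    _, d = _mendelian_variances(ped.sire_idx, ped.dam_idx, F)
    inv_d = 1.0 / d
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        si, di = ped.sire_idx[i], ped.dam_idx[i]
        w = inv_d[i]
        add(i, i, w)
        for p in (si, di):
            if p >= 0:
                add(i, p, -0.5 * w)
                add(p, i, -0.5 * w)
        for p in (si, di):
            if p >= 0:
                for q in (si, di):
                    if q >= 0:
                        add(p, q, 0.25 * w)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    Ainv.sum_duplicates()
    return Ainv


def read_pedigree_csv(path) -> Pedigree:
    """Read an animal,sire,dam CSV (header required; 0/empty = unknown parent)."""
    df = pd.read_csv(path)
    required = {"animal", "sire", "dam"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pedigree file {path} missing column(s): {sorted(missing)}")
    return validate_and_sort(df[["animal", "sire", "dam"]].itertuples(index=False, name=None))


def write_pedigree_csv(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)
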