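"""Pedigree and genomic relationship matrices.

Covers the numerator relationship matrix A (tabular method), its sparse
inverse (Henderson's rules with inbreeding), inbreeding coefficients
(Meuwissen–Luo recursion), the VanRaden genomic relationship matrix
G = ZZ' / (2 * sum p_j (1 - p_j)), blending of G with the pedigree
relationships of the genotyped animals (A22), and the eigenvalue sizing of
core subsets: the number of largest eigenvalues of G whose cumulative sum
reaches a given fraction of trace(G).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .synthpop import GenotypeMatrix

__all__ = [
    "RelationshipMatrix",
    "EigenSizing",
    "build_pedigree",
    "compute_inbreeding",
    "build_A",
    "build_A_inverse",
    "build_G",
    "blend_G",
    "eigen_core_sizes",
]

SYMMETRY_TOL = 1e-10


@dataclass
class RelationshipMatrix:
    """A symmetric relationship matrix with its animal-id order."""

    ids: np.ndarray
    values: np.ndarray
    kind: str = "G_raw"

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        if sp.issparse(self.values):
            return
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape inconsistent with ids")
        if not sp.issparse(self.values):
            asym = np.abs(self.values - self.values.T).max() \
                if self.values.size else 0.0
            if asym > SYMMETRY_TOL:
                raise ValueError(f"matrix not symmetric (max dev {asym:g})")

    @property
    def n(self) -> int:
        return len(self.ids)

    def positions(self, ids) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.ids)}
        try:
            return np.array([pos[a] for a in np.asarray(ids)], dtype=int)
        except KeyError as exc:
            raise KeyError(f"id {exc.args[0]} not in matrix") from exc

    def submatrix(self, ids) -> np.ndarray:
        idx = self.positions(ids)
        return self.values[np.ix_(idx, idx)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def _parent_arrays(ped: pd.DataFrame):
    """0-based parent indices with -1 for unknown; validates topology."""
    animal = ped["animal"].to_numpy()
    n = len(animal)
    if not np.array_equal(animal, np.arange(1, n + 1)):
        raise ValueError("pedigree must be renumbered 1..N (use "
                         "build_pedigree first)")
    sire = ped["sire"].to_numpy() - 1
    dam = ped["dam"].to_numpy() - 1
    own = np.arange(n)
    if ((sire >= own) & (sire >= 0)).any() or ((dam >= own) & (dam >= 0)).any():
        raise ValueError("pedigree not topologically ordered")
    return sire, dam


def build_pedigree(raw: pd.DataFrame):
    """Validate, topologically sort, and renumber a raw pedigree table.

    Parents coded 0 (or missing) are unknown.  Returns the renumbered table
    plus a mapping from original to new ids.  Raises on cycles and on a
    sire recorded as female (or dam as male).
    """
    ped = raw.copy()
    for col, default in (("sex", "U"), ("cohort", 0), ("litter", 0),
                         ("pen", 0), ("genotyped", False),
                         ("phenotyped", False)):
        if col not in ped:
            ped[col] = default
    ped[["sire", "dam"]] = ped[["sire", "dam"]].fillna(0)

    ids = ped["animal"].tolist()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate animal ids")
    known = set(ids)
    sex = dict(zip(ped["animal"], ped["sex"]))
    for s in ped["sire"]:
        if s != 0 and s not in known:
            raise ValueError(f"sire {s} not in pedigree")
    for d in ped["dam"]:
        if d != 0 and d not in known:
            raise ValueError(f"dam {d} not in pedigree")
    for s in set(ped["sire"]) - {0}:
        if sex.get(s) == "F":
            raise ValueError(f"sire {s} recorded as female")
    for d in set(ped["dam"]) - {0}:
        if sex.get(d) == "M":
            raise ValueError(f"dam {d} recorded as male")

    parents = {row.animal: (row.sire, row.dam) for row in ped.itertuples()}
    order: list = []
    state: dict = {}

    def visit(a):
        stack = [(a, iter([p for p in parents[a] if p != 0]))]
        state[a] = 1
        while stack:
            node, it = stack[-1]
            advanced = False
            for p in it:
                st = state.get(p, 0)
                if st == 1:
                    raise ValueError(f"pedigree cycle involving animal {p}")
                if st == 0:
                    state[p] = 1
                    stack.append((p, iter([q for q in parents[p] if q != 0])))
                    advanced = True
                    break
            if not advanced:
                state[node] = 2
                order.append(node)
                stack.pop()

    for a in ids:
        if state.get(a, 0) == 0:
            visit(a)

    id_map = {old: new for new, old in enumerate(order, start=1)}
    ped = ped.set_index("animal").loc[order].reset_index()
    ped["animal"] = ped["animal"].map(id_map)
    ped["sire"] = ped["sire"].map(lambda s: id_map.get(s, 0))
    ped["dam"] = ped["dam"].map(lambda d: id_map.get(d, 0))
    return ped, id_map


def compute_inbreeding(ped: pd.DataFrame) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen–Luo recursion.

    For each animal the diagonal a_ii = 1 + F_i is accumulated as
    sum_j L_j^2 D_j over its ancestors, where L traces expected genome
    contributions and D_j is the Mendelian-sampling variance of ancestor j.
    Founders have F = 0; an animal with any unknown parent has F = 0.
    """
    sire, dam = _parent_arrays(ped)
    n = len(sire)
    F = np.zeros(n)
    D = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0 and d < 0:
            D[i] = 1.0
        elif s < 0:
            D[i] = 0.75 - 0.25 * F[d]
        elif d < 0:
            D[i] = 0.75 - 0.25 * F[s]
        else:
            D[i] = 0.5 - 0.25 * (F[s] + F[d])
        if s < 0 or d < 0:
            F[i] = 0.0
            continue
        # a_ii = sum L^2 D over ancestors of i (including i, L_i = 1);
        # ancestors are processed in descending id order (topological), so
        # every L_j is final when popped.
        L = {i: 1.0}
        a_ii = 0.0
        heap = [-i]
        in_heap = {i}
        while heap:
            j = -heapq.heappop(heap)
            in_heap.discard(j)
            lj = L.pop(j)
            a_ii += lj * lj * D[j]
            for p in (sire[j], dam[j]):
                if p >= 0:
                    L[p] = L.get(p, 0.0) + 0.5 * lj
                    if p not in in_heap:
                        in_heap.add(p)
                        heapq.heappush(heap, -p)
        F[i] = a_ii - 1.0
    return F


def build_A(ped: pd.DataFrame, subset=None) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular (recursive) method.

    ``subset``: optional animal ids; the returned matrix is full A
    restricted to those rows/columns (A22 when subset = genotyped ids).
    """
    sire, dam = _parent_arrays(ped)
    n = len(sire)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            row = 0.5 * (A[s, :i] + A[d, :i])
            diag = 1.0 + 0.5 * A[s, d]
        elif s >= 0:
            row = 0.5 * A[s, :i]
            diag = 1.0
        elif d >= 0:
            row = 0.5 * A[d, :i]
            diag = 1.0
        else:
            row = np.zeros(i)
            diag = 1.0
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = diag
    ids = ped["animal"].to_numpy()
    if subset is not None:
        subset = np.asarray(subset)
        missing = np.setdiff1d(subset, ids)
        if len(missing):
            raise KeyError(f"subset ids not in pedigree: {missing[:5]}")
        idx = subset - 1
        return RelationshipMatrix(subset, A[np.ix_(idx, idx)], kind="A22")
    return RelationshipMatrix(ids, A, kind="A")


def build_A_inverse(ped: pd.DataFrame, F=None) -> RelationshipMatrix:
    """Sparse A-inverse by Henderson's rules accounting for inbreeding.

    The Mendelian-sampling variance of animal i is
    d_i = 0.5 - 0.25 (F_s + F_d) with both parents known,
    0.75 - 0.25 F_p with one parent known, and 1 otherwise; each animal
    contributes alpha = 1/d_i to the (i, i), parent, and parent-pair cells.
    """
    sire, dam = _parent_arrays(ped)
    n = len(sire)
    if F is None:
        F = compute_inbreeding(ped)
    F = np.asarray(F, dtype=float)
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            di = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0:
            di = 0.75 - 0.25 * F[s]
        elif d >= 0:
            di = 0.75 - 0.25 * F[d]
        else:
            di = 1.0
        alpha = 1.0 / di
        add(i, i, alpha)
        for p in (s, d):
            if p >= 0:
                add(i, p, -0.5 * alpha)
                add(p, i, -0.5 * alpha)
                add(p, p, 0.25 * alpha)
        if s >= 0 and d >= 0:
            add(s, d, 0.25 * alpha)
            add(d, s, 0.25 * alpha)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return RelationshipMatrix(ped["animal"].to_numpy(), Ainv, kind="A_inv")


def build_G(genotypes: GenotypeMatrix, p=None) -> RelationshipMatrix:
    """VanRaden (method 1) genomic relationship matrix.

    G = Zc Zc' / (2 sum_j p_j (1 - p_j)), with Zc the dosage matrix centred
    by twice the counted-allele frequency.  Frequencies come from the
    supplied matrix unless given externally.
    """
    if p is None:
        p = genotypes.p
    p = np.asarray(p, dtype=float)
    if ((p <= 0.0) | (p >= 1.0)).any():
        bad = [genotypes.snp_names[j]
               for j in np.flatnonzero((p <= 0.0) | (p >= 1.0))[:5]]
        raise ValueError(
            f"monomorphic SNPs present (e.g. {bad}); filter them out "
            "before building G (GenotypeMatrix.drop_monomorphic)")
    Z = genotypes.dosage.astype(float) - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    G = (Z @ Z.T) / denom
    G = 0.5 * (G + G.T)  # enforce exact symmetry against rounding
    return RelationshipMatrix(genotypes.ids, G, kind="G_raw")


def blend_G(G_raw: RelationshipMatrix, A22: RelationshipMatrix,
            w: float = 0.95) -> RelationshipMatrix:
    """Convex blend w*G + (1-w)*A22 guarding against singular G."""
    if not 0.0 < w <= 1.0:
        raise ValueError("blend weight must be in (0, 1]")
    if not np.array_equal(G_raw.ids, A22.ids):
        raise ValueError("G and A22 id orders do not match")
    values = w * G_raw.values + (1.0 - w) * A22.values
    return RelationshipMatrix(G_raw.ids, values, kind="G_blended")


@dataclass
class EigenSizing:
    """Eigen-spectrum-based core sizes.

    ``sizes[t]`` is the smallest count of largest eigenvalues whose
    cumulative sum reaches fraction t of the total (trace of G).
    """

    thresholds: tuple
    sizes: dict = field(default_factory=dict)
    spectrum: np.ndarray = None

    def size_for(self, threshold: float) -> int:
        return self.sizes[threshold]


def eigen_core_sizes(G: RelationshipMatrix | np.ndarray,
                     thresholds=(0.50, 0.80, 0.90, 0.95, 0.99)) -> EigenSizing:
    """Number of largest eigenvalues explaining each variance fraction."""
    values = G.values if isinstance(G, RelationshipMatrix) else np.asarray(G)
    if values.size == 0:
        raise ValueError("empty matrix")
    thresholds = tuple(thresholds)
    if any(not 0.0 < t <= 1.0 for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1]")
    eig = np.linalg.eigvalsh(values)[::-1]
    eig = np.clip(eig, 0.0, None)
    total = eig.sum()
    if total <= 0:
        raise ValueError("matrix has zero trace; spectrum undefined")
    cum = np.cumsum(eig) / total
    sizes = {}
    for t in thresholds:
        sizes[t] = int(np.searchsorted(cum, t - 1e-12) + 1)
        sizes[t] = min(sizes[t], len(eig))
    return EigenSizing(thresholds=thresholds, sizes=sizes, spectrum=eig)
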