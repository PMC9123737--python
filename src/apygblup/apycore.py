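"""Sparse APY inverse of G and assembly of the ssGBLUP H-inverse.

The APY ("proven and young") recursion conditions the breeding values of
noncore animals on those of a core subset.  Writing G in core/noncore block
form [[Gcc, Gcn], [Gnc, Gnn]], the sparse inverse is

    G_APY^-1 = [[Gcc^-1, 0], [0, 0]]
             + [[-Gcc^-1 Gcn], [I]] Mnn^-1 [[-Gnc Gcc^-1, I]],

where Mnn is diagonal with genomic Mendelian-sampling terms
m_ii = g_ii - g_ic Gcc^-1 g_ci (the Schur-complement diagonal).  Only the
core block is inverted directly, and no noncore-by-noncore off-diagonal is
ever stored.

H^-1 extends the pedigree A^-1 with a genotyped-block correction
(G^-1 - A22^-1); the genomic part may be either the APY assembly or the
direct inverse of (blended) G.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp

from .corepick import CorePartition
from .relmat import RelationshipMatrix

__all__ = [
    "APYInverse",
    "HInverse",
    "mendelian_sampling_diagonal",
    "apy_g_inverse",
    "full_g_inverse",
    "build_h_inverse",
    "pedigree_h_inverse",
]

M_FLOOR = 1e-10


@dataclass
class APYInverse:
    """Sparse representation of the APY inverse of G.

    ``assembled`` is a symmetric CSR matrix over core + noncore animals in
    ``ids`` order (core first); its noncore block is diagonal (1 / m_ii).
    """

    partition: CorePartition
    ids: np.ndarray              # core ids then noncore ids
    Gcc_inv: np.ndarray
    coupling: np.ndarray         # -Gcc^-1 Gcn  (core x noncore)
    m: np.ndarray                # Mendelian-sampling diagonal, noncore
    assembled: sp.csr_matrix

    @property
    def nnz(self) -> int:
        return self.assembled.nnz

    def matrix_for_ids(self, ids) -> sp.csr_matrix:
        """The assembled matrix permuted to an arbitrary order of the same
        genotyped ids."""
        ids = np.asarray(ids)
        pos = {a: i for i, a in enumerate(self.ids)}
        if len(ids) != len(self.ids) or any(a not in pos for a in ids):
            raise ValueError("requested id set does not match the partition")
        perm = np.array([pos[a] for a in ids])
        return self.assembled[perm][:, perm].tocsr()

    def to_coo_records(self):
        """(i-id, j-id, value) triplets of the upper triangle, for text
        export in generic sparse coordinate format."""
        coo = sp.triu(self.assembled).tocoo()
        return zip(self.ids[coo.row], self.ids[coo.col], coo.data)


@dataclass
class HInverse:
    """Combined pedigree + genomic inverse used in the ssGBLUP MME."""

    ids: np.ndarray
    matrix: sp.csr_matrix
    genotyped_ids: np.ndarray


def _core_noncore_positions(G: RelationshipMatrix, partition: CorePartition):
    if not np.array_equal(np.sort(partition.genotyped_ids), np.sort(G.ids)):
        raise ValueError("partition does not cover the id set of G")
    ci = G.positions(partition.core)
    ni = G.positions(partition.noncore)
    return ci, ni


def _chol_core(Gcc: np.ndarray):
    try:
        return scipy.linalg.cho_factor(Gcc, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "core block of G is not positive definite; increase the blending "
            "weight on A22 (blend_G) or change the core") from exc


def mendelian_sampling_diagonal(G: RelationshipMatrix,
                                partition: CorePartition) -> np.ndarray:
    """Genomic Mendelian-sampling terms m_ii = g_ii - g_ic Gcc^-1 g_ci."""
    ci, ni = _core_noncore_positions(G, partition)
    Gcc = G.values[np.ix_(ci, ci)]
    Gcn = G.values[np.ix_(ci, ni)]
    g_nn_diag = G.values[ni, ni]
    cf = _chol_core(Gcc)
    S = scipy.linalg.cho_solve(cf, Gcn)
    m = g_nn_diag - np.einsum("ij,ij->j", Gcn, S)
    _check_m(m, partition)
    return m


def _check_m(m: np.ndarray, partition: CorePartition) -> None:
    bad = np.flatnonzero(m <= M_FLOOR)
    if bad.size:
        culprit = partition.noncore[bad[0]]
        raise ValueError(
            f"Mendelian-sampling term of noncore animal {culprit} is "
            f"{m[bad[0]]:.3e} <= {M_FLOOR:g}: the animal is (numerically) in "
            "the span of the core; move it to the core or blend G")


def apy_g_inverse(G: RelationshipMatrix,
                  partition: CorePartition) -> APYInverse:
    """Assemble the sparse APY inverse for a blended G and a partition."""
    ci, ni = _core_noncore_positions(G, partition)
    Gcc = G.values[np.ix_(ci, ci)]
    Gcn = G.values[np.ix_(ci, ni)]
    cf = _chol_core(Gcc)
    n_core, n_non = len(ci), len(ni)
    Gcc_inv = scipy.linalg.cho_solve(cf, np.eye(n_core))
    Gcc_inv = 0.5 * (Gcc_inv + Gcc_inv.T)

    if n_non == 0:
        assembled = sp.csr_matrix(Gcc_inv)
        return APYInverse(partition, partition.core.copy(), Gcc_inv,
                          np.zeros((n_core, 0)), np.zeros(0), assembled)

    U = -scipy.linalg.cho_solve(cf, Gcn)           # -Gcc^-1 Gcn
    m = G.values[ni, ni] - np.einsum("ij,ij->j", Gcn, -U)
    _check_m(m, partition)
    inv_m = 1.0 / m

    CN = U * inv_m                                  # core x noncore block
    CC = Gcc_inv + CN @ U.T
    CC = 0.5 * (CC + CC.T)
    assembled = sp.bmat(
        [[sp.csr_matrix(CC), sp.csr_matrix(CN)],
         [sp.csr_matrix(CN.T), sp.diags(inv_m, format="csr")]],
        format="csr")
    ids = np.concatenate([partition.core, partition.noncore])
    return APYInverse(partition, ids, Gcc_inv, U, m, assembled)


def full_g_inverse(G: RelationshipMatrix) -> np.ndarray:
    """Direct (dense) inverse of G — the regular ssGBLUP baseline."""
    cf = _chol_core(G.values)
    inv = scipy.linalg.cho_solve(cf, np.eye(G.n))
    return 0.5 * (inv + inv.T)


def build_h_inverse(A_inv: RelationshipMatrix,
                    A22_inv: RelationshipMatrix,
                    G_inv_like,
                    genotyped_ids) -> HInverse:
    """H^-1 = A^-1 + [0 0; 0 G^-1 - A22^-1] on the genotyped block.

    ``G_inv_like`` may be an :class:`APYInverse`, a dense array aligned with
    ``A22_inv.ids``, or a sparse matrix aligned likewise.
    """
    genotyped_ids = np.asarray(genotyped_ids)
    if not np.array_equal(np.sort(genotyped_ids), np.sort(A22_inv.ids)):
        raise ValueError("genotyped ids do not match A22 inverse")
    order = A22_inv.ids
    if isinstance(G_inv_like, APYInverse):
        G_inv = G_inv_like.matrix_for_ids(order).toarray()
    elif sp.issparse(G_inv_like):
        G_inv = G_inv_like.toarray()
    else:
        G_inv = np.asarray(G_inv_like)
    if G_inv.shape != (len(order), len(order)):
        raise ValueError("genomic inverse misaligned with genotyped ids")

    corr = G_inv - A22_inv.values
    ped_pos = {a: i for i, a in enumerate(A_inv.ids)}
    missing = [a for a in order if a not in ped_pos]
    if missing:
        raise ValueError(f"genotyped ids missing from pedigree: {missing[:5]}")
    gpos = np.array([ped_pos[a] for a in order])
    n = len(A_inv.ids)
    rows = np.repeat(gpos, len(gpos))
    cols = np.tile(gpos, len(gpos))
    corr_sp = sp.coo_matrix((corr.ravel(), (rows, cols)), shape=(n, n))
    H = (A_inv.values + corr_sp).tocsr()
    return HInverse(A_inv.ids, H, order)


def pedigree_h_inverse(A_inv: RelationshipMatrix) -> HInverse:
    """Pedigree-only baseline: H^-1 = A^-1 (no genomic correction)."""
    return HInverse(A_inv.ids, sp.csr_matrix(A_inv.values),
                    np.empty(0, dtype=A_inv.ids.dtype))
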