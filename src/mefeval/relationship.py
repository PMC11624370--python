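"""Pedigree, genomic and combined relationship matrices for (ss)GBLUP.

Provides inbreeding coefficients (Meuwissen-Luo style ancestor tracing), the
dense numerator relationship matrix A (tabular method), its sparse inverse
from Henderson's rules with inbreeding, the VanRaden genomic relationship
matrix G with tuning/blending to A22, and the single-step H inverse

    H^-1 = A^-1 + [0 0; 0 G*^-1 - A22^-1]

on the genotyped block.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .pedigree import PedigreeTable


@dataclass
class SparseSymmetric:
    """Sparse symmetric matrix keyed by entity ids (one row per id)."""

    matrix: sp.csr_matrix
    ids: np.ndarray

    def __post_init__(self):
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.ids):
            raise ValueError("dimension does not match the id map")
        asym = abs(m - m.T)
        if asym.nnz and asym.max() > 1e-8 * max(1.0, abs(m).max()):
            raise ValueError("matrix is not symmetric")

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()

    def to_coordinate_text(self, path) -> None:
        coo = self.matrix.tocoo()
        with open(path, "w") as fh:
            fh.write(f"# dim {self.dim}\n")
            for i, j, v in zip(coo.row, coo.col, coo.data):
                if i <= j:
                    fh.write(f"{self.ids[i]} {self.ids[j]} {v:.12g}\n")


def _mendelian_d(si: int, di: int, f: np.ndarray) -> float:
    """Mendelian-sampling variance coefficient given known-parent pattern."""
    if si >= 0 and di >= 0:
        return 0.5 - 0.25 * (f[si] + f[di])
    if si >= 0 or di >= 0:
        return 0.75 - 0.25 * f[max(si, di)]
    return 1.0


def inbreeding_coefficients(pedigree: PedigreeTable) -> np.ndarray:
    """Per-animal inbreeding coefficients F.

    Ancestor-tracing computation of the diagonal of A (Meuwissen-Luo):
    A_ii = sum_j L_ij^2 D_j over the ancestors j of i, accumulated by
    propagating path coefficients from i up the pedigree; F_i = A_ii - 1.
    Animals with an unknown parent have F = 0 by construction.
    """
    ped = pedigree.sorted()
    si, di = ped.parent_indices()
    n = len(ped)
    f = np.zeros(n)
    d = np.zeros(n)
    for i in range(n):
        d[i] = _mendelian_d(si[i], di[i], f)
        if si[i] < 0 or di[i] < 0:
            f[i] = 0.0
            continue
        # trace ancestors of i, youngest first
        coeff = {i: 1.0}
        heap = [-i]
        seen = {i}
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            lj = coeff.pop(j)
            aii += lj * lj * d[j]
            for p in (si[j], di[j]):
                if p >= 0:
                    if p not in coeff:
                        coeff[p] = 0.0
                    coeff[p] += 0.5 * lj
                    if p not in seen:
                        seen.add(p)
                        heapq.heappush(heap, -p)
        f[i] = aii - 1.0
    # return in the caller's original order
    if ped is not pedigree:
        back = pedigree.index_of(ped.animals)
        out = np.empty(n)
        out[back] = f
        return out
    return f


def numerator_relationship(pedigree: PedigreeTable) -> np.ndarray:
    """Dense A by the tabular method (diag(A) = 1 + F).

    Intended for small pedigrees (tests, A22 blocks for H); the input is
    sorted internally if parents do not precede offspring.
    """
    ped = pedigree.sorted()
    si, di = ped.parent_indices()
    n = len(ped)
    a = np.zeros((n, n))
    for i in range(n):
        row = np.zeros(i)
        if si[i] >= 0:
            row += 0.5 * a[si[i], :i]
        if di[i] >= 0:
            row += 0.5 * a[di[i], :i]
        a[i, :i] = row
        a[:i, i] = row
        diag = 1.0
        if si[i] >= 0 and di[i] >= 0:
            diag += 0.5 * a[si[i], di[i]]
        a[i, i] = diag
    if ped is not pedigree:
        perm = ped.index_of(pedigree.animals)
        a = a[np.ix_(perm, perm)]
    return a


def numerator_relationship_inverse(
    pedigree: PedigreeTable, f: np.ndarray | None = None
) -> SparseSymmetric:
    """Sparse A^-1 from Henderson's rules with inbreeding accounted for."""
    ped = pedigree.sorted()
    if f is None:
        f = inbreeding_coefficients(ped)
    si, di = ped.parent_indices()
    n = len(ped)
    rows, cols, vals = [], [], []
    for i in range(n):
        alpha = 1.0 / _mendelian_d(si[i], di[i], f)
        parents = [p for p in (si[i], di[i]) if p >= 0]
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
    m = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    out = SparseSymmetric(m, ped.animals)
    if ped is not pedigree:
        perm = ped.index_of(pedigree.animals)
        out = SparseSymmetric(m[perm][:, perm].tocsr(), pedigree.animals)
    return out


def a22_block(pedigree: PedigreeTable, genotyped_ids) -> np.ndarray:
    """Pedigree relationships among the genotyped animals (dense)."""
    a = numerator_relationship(pedigree)
    idx = pedigree.index_of(genotyped_ids)
    return a[np.ix_(idx, idx)]


def genomic_relationship(
    genotypes: np.ndarray,
    allele_freqs: np.ndarray | None = None,
    a22: np.ndarray | None = None,
    blend_weight: float = 0.05,
    tune: bool = True,
) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix, optionally tuned and
    blended with A22.

    G = ZZ' / (2 sum p(1-p)) with Z = M - 2p.  When ``tune`` is set and A22
    is given, G is linearly adjusted so its mean diagonal and off-diagonal
    match A22 before blending G* = (1-w) G + w A22 (w>0 guarantees G*
    invertible when A22 is).
    """
    m = np.asarray(genotypes, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need a genotype matrix with at least 2 animals")
    if allele_freqs is None:
        allele_freqs = m.mean(axis=0) / 2.0
    p = np.asarray(allele_freqs, dtype=float)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic: cannot scale G")
    z = m - 2.0 * p
    g = (z @ z.T) / denom
    if a22 is not None:
        if tune:
            n = g.shape[0]
            off = ~np.eye(n, dtype=bool)
            md_g, mo_g = g.diagonal().mean(), g[off].mean() if n > 1 else 0.0
            md_a, mo_a = a22.diagonal().mean(), a22[off].mean() if n > 1 else 0.0
            if abs(md_g - mo_g) > 1e-12:
                beta = (md_a - mo_a) / (md_g - mo_g)
                alpha = md_a - beta * md_g
                g = beta * g + alpha
        if not (0 <= blend_weight <= 1):
            raise ValueError("blend_weight must be in [0,1]")
        g = (1.0 - blend_weight) * g + blend_weight * a22
    return g


def h_inverse(
    a_inv: SparseSymmetric,
    a22: np.ndarray,
    g_star: np.ndarray,
    genotyped_ids,
) -> SparseSymmetric:
    """Single-step H^-1 = A^-1 + [0 0; 0 G*^-1 - A22^-1] (genotyped block)."""
    ids = np.asarray(a_inv.ids)
    pos = {a: i for i, a in enumerate(ids)}
    gids = np.asarray(genotyped_ids)
    missing = [g for g in gids if g not in pos]
    if missing:
        raise ValueError(f"genotyped ids not in pedigree: {missing[:5]}")
    idx = np.array([pos[g] for g in gids])
    if len(gids) == 0:
        return a_inv
    delta = np.linalg.inv(g_star) - np.linalg.inv(a22)
    n = a_inv.dim
    add = sp.coo_matrix(
        (delta.ravel(), (np.repeat(idx, len(idx)), np.tile(idx, len(idx)))),
        shape=(n, n),
    )
    h = (a_inv.matrix + add).tocsr()
    return SparseSymmetric(h, ids)


def h_dense_oracle(a: np.ndarray, g_star: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Dense H from the joint distribution (reference construction).

    Conditioning pedigree BVs of non-genotyped animals on the genotyped
    block: H11 = A11 + A12 A22^-1 (G* - A22) A22^-1 A21, H12 = A12 A22^-1 G*.
    """
    n = a.shape[0]
    mask = np.zeros(n, dtype=bool)
    mask[idx] = True
    nidx = np.flatnonzero(~mask)
    a22 = a[np.ix_(idx, idx)]
    a12 = a[np.ix_(nidx, idx)]
    a22i = np.linalg.inv(a22)
    h = np.zeros_like(a)
    h[np.ix_(idx, idx)] = g_star
    h[np.ix_(nidx, idx)] = a12 @ a22i @ g_star
    h[np.ix_(idx, nidx)] = h[np.ix_(nidx, idx)].T
    h[np.ix_(nidx, nidx)] = (
        a[np.ix_(nidx, nidx)] + a12 @ a22i @ (g_star - a22) @ a22i @ a12.T
    )
    return h
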