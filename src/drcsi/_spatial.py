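"""In-plane neighborhood graph over masked voxels.

Spatial regularization couples each voxel to its 4-connected in-plane
neighbors (no coupling across slices).  The Laplacian L is built over the
masked voxels in C-order of ``np.argwhere(mask)``, matching the (N, ...)
layout produced by ``data[mask]``.  For amplitude matrices F (N rows), the
per-voxel neighborhood penalty of the objective,
``sum_i sum_{j in Delta i} ||F_j - F_i||^2`` (each unordered pair counted
twice), equals ``2 * trace(F^T L F)``.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["masked_laplacian", "neighbor_pairs", "ShiftedLaplacianSolver"]


def neighbor_pairs(mask: np.ndarray) -> np.ndarray:
    """Unordered in-plane 4-neighbor pairs as an (n_pairs, 2) index array.

    Indices refer to the masked-voxel enumeration (C-order of argwhere).
    """
    mask = np.asarray(mask, dtype=bool)
    order = -np.ones(mask.shape, dtype=np.int64)
    order[mask] = np.arange(mask.sum())
    pairs = []
    for axis in (0, 1):  # in-plane axes only
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        a = order[tuple(sl_a)]
        b = order[tuple(sl_b)]
        ok = (a >= 0) & (b >= 0)
        pairs.append(np.column_stack([a[ok], b[ok]]))
    if not pairs:
        return np.zeros((0, 2), dtype=np.int64)
    return np.concatenate(pairs, axis=0)


class ShiftedLaplacianSolver:
    """Exact solver for (I + a L) X = B with the masked in-plane Laplacian.

    Uses a banded Cholesky factorization (the C-order voxel enumeration
    keeps the bandwidth near the mask's row length); falls back to sparse LU
    for wide masks.  The operator is SPD for a >= 0.
    """

    _BAND_LIMIT = 200

    def __init__(self, L: sp.spmatrix, a: float):
        import scipy.linalg as sla
        from scipy.sparse.linalg import splu

        self.a = a
        n = L.shape[0]
        A = (sp.identity(n, format="csr") + a * L).tocoo()
        bw = int(np.abs(A.row - A.col).max()) if A.nnz else 0
        if bw <= self._BAND_LIMIT:
            ab = np.zeros((bw + 1, n))
            upper = A.col >= A.row
            ab[bw - (A.col[upper] - A.row[upper]), A.col[upper]] = A.data[upper]
            self._chol = sla.cholesky_banded(ab)
            self._solve = lambda B: sla.cho_solve_banded((self._chol, False), B)
        else:
            lu = splu(A.tocsc())
            self._solve = lu.solve

    def solve(self, B: np.ndarray) -> np.ndarray:
        return self._solve(B)


def masked_laplacian(mask: np.ndarray) -> sp.csr_matrix:
    """Graph Laplacian of the in-plane 4-connectivity graph on the mask."""
    n = int(np.asarray(mask, bool).sum())
    pairs = neighbor_pairs(mask)
    if pairs.size == 0:
        return sp.csr_matrix((n, n))
    i = np.concatenate([pairs[:, 0], pairs[:, 1]])
    j = np.concatenate([pairs[:, 1], pairs[:, 0]])
    w = np.ones(i.size)
    A = sp.coo_matrix((w, (i, j)), shape=(n, n)).tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    return sp.diags(deg) - A
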