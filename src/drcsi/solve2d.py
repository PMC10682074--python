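"""2D correlation-spectrum inversion with marginal constraints.

The 2D problem estimates a 60 x 60 correlation spectrum per voxel from 64
signals.  Because the 1D subproblems (60 unknowns from 8 signals) are far
less ill-conditioned, their solutions are used to regularize the 2D fit
through L1 penalties on the discrete marginals:

    min_{F >= 0}  sum_i ( ||M_i - K F_i||_2^2
                  + lambda_s * sum_{j in Delta_i} ||F_j - F_i||_2^2
                  + lambda_m ||pi_1 F_i - F_i^1||_1
                  + lambda_m ||pi_2 F_i - F_i^2||_1 ),

with pi_1 / pi_2 summing the 2D amplitudes over the second / first grid
axis.  Defaults: lambda_s = 0.01 (reduced versus 1D, since the marginals
already regularize) and lambda_m = 1000 (marginals are kept close to the 1D
solutions while the joint distribution inside the 2D plane stays free).

The objective is a sum of five convex terms, each with a cheap proximal
map, minimized by product-space (consensus) Douglas-Rachford splitting:
data term (small-system solve via the Woodbury identity, P << Q),
non-negativity (projection), spatial coupling (banded Cholesky solve of the
shifted Laplacian) and the two marginal penalties (soft-thresholding in
marginal space, lifted back through the semi-orthogonal adjoint of pi).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

from ._spatial import ShiftedLaplacianSolver, masked_laplacian
from .kernel import Kernel
from .volumes import SignalVolume, SpectrumField

__all__ = [
    "SolverConfig2D",
    "DRLog",
    "marginal_project",
    "solve_2d_dr",
    "objective_2d",
    "rank1_initialization",
]


@dataclass
class SolverConfig2D:
    """Douglas-Rachford settings for the 2D problem."""

    lambda_s: float = 0.01
    lambda_m: float = 1.0e3
    step: float = 1.0
    relaxation: float = 1.0
    max_iter: int = 3000
    tol: float = 1e-6
    init: str = "marginal"  # 'marginal' (rank-1 outer product) or 'zero'
    polish: bool = True  # active-set polish in the fully unregularized case
    log_objective_every: int = 25

    def __post_init__(self):
        if self.lambda_s < 0 or self.lambda_m < 0:
            raise ValueError("regularization weights must be >= 0")
        if self.step <= 0:
            raise ValueError("step size must be positive")
        if not 0 < self.relaxation <= 2:
            raise ValueError("relaxation must lie in (0, 2]")


@dataclass
class DRLog:
    converged: bool = False
    n_iter: int = 0
    rel_change: list = field(default_factory=list)
    objective: list = field(default_factory=list)  # (iteration, value)

    def to_frame(self) -> pd.DataFrame:
        obj = dict(self.objective)
        return pd.DataFrame(
            {
                "iteration": np.arange(len(self.rel_change)),
                "rel_change": self.rel_change,
                "objective": [obj.get(i, np.nan) for i in range(len(self.rel_change))],
            }
        )

    def to_table(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def marginal_project(F2d: np.ndarray, grid, axis: int) -> np.ndarray:
    """Discrete marginal of a 2D spectrum: sum over the *other* grid axis.

    ``axis=1`` returns the marginal along the first grid axis (summing the
    second), ``axis=2`` the marginal along the second.  Works on any leading
    voxel dimensions; total mass is preserved.
    """
    if grid.ndim != 2:
        raise ValueError("marginal projection requires a 2D grid")
    n1, n2 = grid.shape
    F2d = np.asarray(F2d, dtype=float)
    if F2d.shape[-1] != n1 * n2:
        raise ValueError(
            f"flat spectrum length {F2d.shape[-1]} does not match grid "
            f"{n1}x{n2} (row-major layout expected)"
        )
    R = F2d.reshape(F2d.shape[:-1] + (n1, n2))
    if axis == 1:
        return R.sum(axis=-1)
    if axis == 2:
        return R.sum(axis=-2)
    raise ValueError("axis must be 1 or 2")


def _lift(m: np.ndarray, shape: tuple[int, int], axis: int) -> np.ndarray:
    """Adjoint of the marginal projection: broadcast back to the 2D grid."""
    n1, n2 = shape
    if axis == 1:
        return np.repeat(m[..., :, None], n2, axis=-1).reshape(m.shape[:-1] + (n1 * n2,))
    return np.repeat(m[..., None, :], n1, axis=-2).reshape(m.shape[:-1] + (n1 * n2,))


def objective_2d(
    F: np.ndarray,
    M: np.ndarray,
    kernel: Kernel,
    L: sp.spmatrix,
    lambda_s: float,
    lambda_m: float,
    F1: np.ndarray,
    F2: np.ndarray,
) -> float:
    """Value of the 2D objective at amplitudes F (N, Q)."""
    K = kernel.matrix
    grid = kernel.grid
    val = float(np.sum((M - F @ K.T) ** 2))
    if lambda_s > 0:
        val += 2.0 * lambda_s * float(np.sum(F * (L @ F)))
    if lambda_m > 0:
        val += lambda_m * float(np.abs(marginal_project(F, grid, 1) - F1).sum())
        val += lambda_m * float(np.abs(marginal_project(F, grid, 2) - F2).sum())
    return val


def rank1_initialization(F1: np.ndarray, F2: np.ndarray) -> np.ndarray:
    """Per-voxel outer product of the 1D marginals, rescaled to the voxel's
    mean 1D mass; zero where either marginal is empty."""
    m1 = F1.sum(axis=-1)
    m2 = F2.sum(axis=-1)
    denom = m1 * m2
    scale = np.where(denom > 0, (m1 + m2) / 2.0 / np.where(denom > 0, denom, 1.0), 0.0)
    outer = F1[..., :, None] * F2[..., None, :]
    out = outer * scale[..., None, None]
    return out.reshape(F1.shape[:-1] + (F1.shape[-1] * F2.shape[-1],))


def solve_2d_dr(
    signals: SignalVolume,
    kernel2d: Kernel,
    marginals: tuple[SpectrumField, SpectrumField],
    config: SolverConfig2D | None = None,
    full_output: bool = False,
):
    """Solve the marginal-constrained 2D spectral problem.

    Parameters
    ----------
    signals : SignalVolume
        Preprocessed signals with all P (typically 64) contrasts.
    kernel2d : Kernel
        Forward kernel on the 2D correlation grid.
    marginals : (SpectrumField, SpectrumField)
        The 1D solutions along the first and second grid axis, on 1D grids
        matching the respective axes of ``kernel2d.grid``.
    config : SolverConfig2D, optional
    full_output : bool
        Also return the :class:`DRLog`.

    Returns
    -------
    SpectrumField with F >= 0 (the consensus iterate projected onto the
    non-negative orthant, which every outer iteration maintains).
    """
    config = config or SolverConfig2D()
    grid = kernel2d.grid
    if grid.ndim != 2:
        raise ValueError("solve_2d_dr requires a 2D kernel grid")
    f1, f2 = marginals
    for fld, ax, k in ((f1, grid.axes[0], 1), (f2, grid.axes[1], 2)):
        if fld.grid.ndim != 1 or fld.grid.axes[0].name != ax.name or fld.grid.axes[0].n != ax.n:
            raise ValueError(
                f"marginal {k} grid does not match 2D grid axis {ax.name!r}"
            )
        if fld.mask.shape != signals.mask.shape or not np.array_equal(
            fld.mask, signals.mask
        ):
            raise ValueError(f"marginal {k} mask does not match the signal mask")

    M = signals.masked()
    if not np.all(np.isfinite(M)):
        raise ValueError("signals contain non-finite values")
    K = kernel2d.matrix
    N, Q = M.shape[0], grid.Q
    n1, n2 = grid.shape
    L = masked_laplacian(signals.mask)
    F1 = f1.masked()
    F2 = f2.masked()

    t = config.step
    lam_s, lam_m = config.lambda_s, config.lambda_m

    # data prox via Woodbury: (I + c K^T K)^{-1} = I - K^T (I/c + K K^T)^{-1} K
    c = 2.0 * t
    cho = sla.cho_factor(np.eye(K.shape[0]) / c + K @ K.T, lower=True)
    KtM = M @ K  # (N, Q), constant shift 2 K^T M per voxel

    def prox_data(X):
        G = X + c * KtM
        S = sla.cho_solve(cho, (G @ K.T).T).T  # (N, P)
        return G - S @ K

    def prox_nonneg(X):
        return np.maximum(X, 0.0)

    a_sp = 4.0 * t * lam_s
    sp_solver = (
        ShiftedLaplacianSolver(L, a_sp) if (lam_s > 0 and L.nnz > 0) else None
    )

    def prox_spatial(X):
        if sp_solver is None:
            return X.copy()
        return sp_solver.solve(X)

    def make_prox_marginal(axis, target, nu):
        thr = t * nu * lam_m

        def prox(X):
            if lam_m == 0:
                return X.copy()
            PX = marginal_project(X, grid, axis)
            u = PX - target
            shrunk = np.sign(u) * np.maximum(np.abs(u) - thr, 0.0)
            corrected = target + shrunk  # prox of lam_m||. - target||_1 at PX
            return X + _lift((corrected - PX) / nu, (n1, n2), axis)

        return prox

    proxes = [
        prox_data,
        prox_nonneg,
        prox_spatial,
        make_prox_marginal(1, F1, n2),
        make_prox_marginal(2, F2, n1),
    ]

    if config.init == "marginal":
        F0 = rank1_initialization(F1, F2)
    elif config.init == "zero":
        F0 = np.zeros((N, Q))
    else:
        raise ValueError("init must be 'marginal' or 'zero'")

    Zs = [F0.copy() for _ in proxes]
    n_blocks = len(proxes)
    Zsum = F0 * n_blocks
    x = F0.copy()
    alpha = config.relaxation
    log = DRLog()

    for it in range(config.max_iter):
        x_old = x
        x = Zsum / n_blocks
        for k, prox in enumerate(proxes):
            p = prox(2.0 * x - Zs[k])
            p -= x
            p *= alpha
            Zs[k] += p
            Zsum += p
        rel = np.linalg.norm(x - x_old) / max(np.linalg.norm(x_old), 1e-12)
        log.rel_change.append(rel)
        if config.log_objective_every and (it % config.log_objective_every == 0):
            log.objective.append(
                (it, objective_2d(np.maximum(x, 0), M, kernel2d, L, lam_s, lam_m, F1, F2))
            )
        if it > 0 and rel <= config.tol:
            log.converged = True
            log.n_iter = it + 1
            break
    else:
        log.n_iter = config.max_iter

    F = np.maximum(Zsum / n_blocks, 0.0)
    if config.polish and lam_s == 0.0 and lam_m == 0.0:
        # voxels decouple into plain non-negative least squares; refine the
        # spread splitting iterate to the active-set vertex (see solve1d)
        from .solve1d import _polish_active_set

        F = _polish_active_set(F, M, K)
    log.objective.append(
        (log.n_iter, objective_2d(F, M, kernel2d, L, lam_s, lam_m, F1, F2))
    )
    field = SpectrumField(
        data=np.zeros(signals.shape + (Q,)), mask=signals.mask.copy(), grid=grid
    )
    field.data[signals.mask] = F
    if full_output:
        return field, log
    return field
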