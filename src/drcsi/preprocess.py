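"""Signal conditioning: powder averaging, polarity recovery, normalization.

The spectral solvers expect real-valued, voxel-wise L2-normalized signal
vectors.  Raw magnitude data are conditioned in three steps:

1. ``powder_average`` -- arithmetic mean over the diffusion directions of
   each b-shell, removing orientation dependence.
2. ``polarity_correct`` -- inversion-recovery magnitude data lose the sign of
   signals acquired before the T1 null crossing (TI < T1 ln 2 for TR >> T1).
   Signs are restored per voxel by testing every monotone sign pattern in TI
   (negative then positive, at most one change) against a small
   multi-exponential dictionary fit and keeping the pattern with the lowest
   non-negative least-squares residual.
3. ``l2_normalize`` -- each voxel divided by the Euclidean norm of its signal
   vector, removing per-voxel scale (M0, coil gain) so only relative decays
   remain.

``extract_1d_subset`` pulls the 8 contrasts of a 1D subproblem out of an
8 x 8 product protocol (the other scan parameter held at its minimum).
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .kernel import build_kernel
from .phantom import RawDataset
from .protocol import AcquisitionProtocol, AxisSpec, SpectralGrid
from .volumes import SignalVolume

__all__ = [
    "powder_average",
    "polarity_correct",
    "l2_normalize",
    "extract_1d_subset",
]


def powder_average(raw: RawDataset) -> SignalVolume:
    """Average the per-direction volumes of each contrast.

    Contrasts acquired with a single direction pass through unchanged.
    Raises if the volume table does not supply every direction of every
    contrast of the protocol.
    """
    protocol = raw.protocol
    P = protocol.P
    data = np.zeros(raw.data.shape[:3] + (P,), dtype=float)
    counts = raw.volumes.groupby("contrast")["volume"].count()
    for p in range(P):
        expected = int(protocol.n_directions[p])
        got = int(counts.get(p, 0))
        if got != expected:
            raise ValueError(
                f"contrast {p}: expected {expected} direction volumes, found {got}"
            )
        vols = raw.volumes.loc[raw.volumes["contrast"] == p, "volume"].to_numpy()
        data[..., p] = raw.data[..., vols].mean(axis=-1)
    return SignalVolume(
        data=data,
        mask=raw.mask.copy(),
        protocol=protocol,
        powder_averaged=True,
        polarity_corrected=not protocol.has_inversion,
    )


def _coarse_dictionary(protocol: AcquisitionProtocol, n_t1=12, n_other=6):
    """Small signed dictionary kernel for the polarity fit."""
    from .protocol import DEFAULT_AXIS_RANGES

    axes = [AxisSpec("T1", *DEFAULT_AXIS_RANGES["T1"], n=n_t1)]
    varied = protocol.varied_axes()
    for axis in ("T2", "D"):
        if axis in varied:
            axes.append(AxisSpec(axis, *DEFAULT_AXIS_RANGES[axis], n=n_other))
    grid = SpectralGrid(axes=tuple(axes[:2]))
    return build_kernel(protocol, grid).matrix


def polarity_correct(
    signals: SignalVolume, n_t1: int = 12, n_other: int = 6
) -> SignalVolume:
    """Restore inversion-recovery signal polarity on magnitude data.

    For each masked voxel, every monotone sign pattern over the sorted
    inversion times (all contrasts sharing a TI flip together; signs are
    negative below the crossing, positive above) is scored by the residual
    of a non-negative least-squares fit to a coarse multi-exponential
    dictionary built from the protocol; the minimizing pattern is applied.

    Idempotent: already-corrected volumes are returned unchanged.  A
    protocol without inversion preparation is a no-op (with a warning).
    """
    if signals.polarity_corrected:
        return signals.copy()
    if not signals.protocol.has_inversion:
        warnings.warn("protocol has no inversion pulses; polarity is a no-op")
        return replace(signals.copy(), polarity_corrected=True)

    protocol = signals.protocol
    K = _coarse_dictionary(protocol, n_t1=n_t1, n_other=n_other)
    ti = protocol.TI
    finite = np.isfinite(ti)
    t_sorted = np.unique(ti[finite])
    # rank of each contrast's TI among the sorted unique TIs (nan -> +inf rank)
    rank = np.full(protocol.P, t_sorted.size, dtype=int)
    rank[finite] = np.searchsorted(t_sorted, ti[finite])

    patterns = []
    for c in range(t_sorted.size + 1):
        s = np.where(rank < c, -1.0, 1.0)
        patterns.append(s)

    M = np.abs(signals.masked())
    out = M.copy()
    norms = np.linalg.norm(M, axis=1)
    for i in range(M.shape[0]):
        if norms[i] == 0:
            continue
        best, best_res = None, np.inf
        for s in patterns:
            _, res = _scipy_nnls(K, s * M[i])
            if res < best_res:
                best, best_res = s, res
        out[i] = best * M[i]
    return signals.with_masked(out, polarity_corrected=True)


def l2_normalize(
    signals: SignalVolume, rel_tolerance: float = 1e-8
) -> SignalVolume:
    """Divide each masked voxel by the L2 norm of its signal vector.

    Voxels whose norm falls below ``rel_tolerance * max_norm`` are removed
    from the mask (background noise must not be inflated to unit norm).
    """
    M = signals.masked()
    norms = np.linalg.norm(M, axis=1)
    max_norm = norms.max() if norms.size else 0.0
    keep = norms > rel_tolerance * max_norm
    data = np.zeros_like(signals.data)
    mask = np.zeros_like(signals.mask)
    idx = np.argwhere(signals.mask)
    kept_idx = idx[keep]
    mask[tuple(kept_idx.T)] = True
    data[tuple(kept_idx.T)] = M[keep] / norms[keep, None]
    return SignalVolume(
        data=data,
        mask=mask,
        protocol=signals.protocol,
        polarity_corrected=signals.polarity_corrected,
        powder_averaged=signals.powder_averaged,
        normalized=True,
    )


def extract_1d_subset(
    signals: SignalVolume, keep: str, sign_convention: bool = True
) -> SignalVolume:
    """Extract the 8-contrast 1D subproblem for tissue axis ``keep``.

    From an n x m product protocol, selects the contrasts where the scan
    parameter encoding the *other* varied axis sits at its minimum value
    (the first row/column of the 2D contrast grid), sorted by the kept
    parameter.  Q/P drops from 3600/64 to 60/8 on the default grids.

    When the extracted subset no longer varies TI but carries a fixed
    negative inversion weighting (signals predominantly negative), the
    voxel sign is flipped so non-negative spectral amplitudes can represent
    the data; the flip is a per-voxel overall sign, absorbed into the
    amplitudes (``sign_convention=True``, default).
    """
    protocol = signals.protocol
    varied = protocol.varied_axes()
    if keep not in varied:
        raise ValueError(f"axis {keep!r} is not varied by protocol {protocol.name!r}")
    if len(varied) != 2:
        raise ValueError(
            f"protocol {protocol.name!r} is not a 2-axis product design "
            f"(varied axes: {varied})"
        )
    other = [a for a in varied if a != keep][0]
    pk = protocol.parameter(keep)
    po = protocol.parameter(other)
    n_k = np.unique(pk[np.isfinite(pk)]).size
    n_o = np.unique(po[np.isfinite(po)]).size
    if n_k * n_o != protocol.P:
        raise ValueError("protocol is not a full Cartesian product design")
    o_min = np.nanmin(po)
    sel = np.where(po == o_min)[0]
    sel = sel[np.argsort(pk[sel])]
    sub_protocol = protocol.subset(sel, name=f"{protocol.name}-{keep.lower()}1d")

    data = signals.data[..., sel]
    sub = SignalVolume(
        data=data.copy(),
        mask=signals.mask.copy(),
        protocol=sub_protocol,
        polarity_corrected=signals.polarity_corrected,
        powder_averaged=signals.powder_averaged,
        normalized=signals.normalized,
    )
    ti = sub_protocol.TI
    ti_varied = "T1" in sub_protocol.varied_axes()
    if sign_convention and not ti_varied:
        M = sub.masked()
        flip = M.sum(axis=1) < 0
        M[flip] *= -1.0
        sub = sub.with_masked(M)
    return sub
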