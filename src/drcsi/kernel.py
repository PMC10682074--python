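"""Forward model: the DW-IR-SE signal kernel.

Each measured contrast p with parameters (TI_p, TE_p, b_p) weights a tissue
component q = (T1_q, T2_q, D_q) by the product of three exponential factors::

    K(p, q) = (1 - 2 exp(-TI_p / T1_q) + exp(-TR / T1_q))   # inversion recovery
              * exp(-TE_p / T2_q)                            # T2 decay
              * exp(-b_p * D_q)                              # diffusion decay

The IR factor lies in (-1, 2) and is negative before the T1 null crossing at
TI = T1 ln 2 (for TR >> T1); the decay factors lie in (0, 1].  Signals are
linear in the spectral amplitudes, so simulation is the matrix product
M = K F per voxel.

Units: TI, TE, TR in ms; T1, T2 in ms; b in s mm^-2 and D in um^2 ms^-1, with
b converted internally to ms um^-2 (b = 1000 s mm^-2 equals 1 ms um^-2) so
that b * D is dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import AcquisitionProtocol, SpectralGrid

__all__ = ["Kernel", "ir_factor", "build_kernel", "simulate_signals", "B_TO_MS_PER_UM2"]

#: b-value conversion: s mm^-2 -> ms um^-2.
B_TO_MS_PER_UM2 = 1.0e-3


def ir_factor(TI, TR, T1):
    """Inversion-recovery longitudinal weighting.

    Returns ``1 - 2 exp(-TI/T1) + exp(-TR/T1)``; exactly 1 when *TI* is None
    or nan (no inversion pulse).  Accepts scalars or broadcastable arrays;
    nan entries in an array *TI* likewise yield 1.
    """
    T1 = np.asarray(T1, dtype=float)
    if np.any(T1 <= 0):
        raise ValueError("T1 must be positive")
    if np.any(np.asarray(TR, dtype=float) <= 0):
        raise ValueError("TR must be positive")
    if TI is None:
        return np.ones_like(T1) if T1.ndim else 1.0
    TI = np.asarray(TI, dtype=float)
    with np.errstate(invalid="ignore"):
        out = 1.0 - 2.0 * np.exp(-TI / T1) + np.exp(-np.asarray(TR, float) / T1)
    out = np.where(np.isnan(TI), 1.0, out)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class Kernel:
    """Dense P x Q forward operator tied to a protocol and a grid."""

    matrix: np.ndarray
    protocol: AcquisitionProtocol
    grid: SpectralGrid

    @property
    def P(self) -> int:
        return self.matrix.shape[0]

    @property
    def Q(self) -> int:
        return self.matrix.shape[1]

    def to_table(self, path=None, fmt="%.12e") -> str:
        """Export the matrix as delimited text for external cross-checks."""
        import io as _io

        buf = _io.StringIO()
        np.savetxt(buf, self.matrix, fmt=fmt, delimiter="\t")
        text = buf.getvalue()
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def build_kernel(
    protocol: AcquisitionProtocol,
    grid: SpectralGrid,
    nuisance: dict | None = None,
) -> Kernel:
    """Assemble the DW-IR-SE kernel on a spectral grid.

    Axes absent from the grid contribute factor 1: when the corresponding
    scan parameter is constant across the protocol its decay is a fixed
    per-component scale that is absorbed into the (non-negative) amplitudes.
    If the protocol *varies* a parameter whose tissue axis is not on the
    grid, a fixed nuisance tissue value must be supplied via ``nuisance``
    (e.g. ``{"T2": 70.0}``), otherwise the model would be underdetermined
    and an error is raised.
    """
    nuisance = dict(nuisance or {})
    names = grid.axis_names
    for axis in ("T1", "T2", "D"):
        if axis in names:
            continue
        if axis in protocol.varied_axes() and axis not in nuisance:
            raise ValueError(
                f"protocol varies the scan parameter encoding {axis} but the "
                f"grid has no {axis} axis; supply nuisance={{'{axis}': value}}"
            )

    P, Q = protocol.P, grid.Q

    def comp(axis):
        if axis in names:
            return grid.component_values(axis)
        if axis in nuisance:
            return np.full(Q, float(nuisance[axis]))
        return None  # absorbed

    T1 = comp("T1")
    T2 = comp("T2")
    D = comp("D")

    K = np.ones((P, Q), dtype=float)
    if T1 is not None:
        K *= ir_factor(protocol.TI[:, None], protocol.TR, T1[None, :])
    else:
        # no T1 axis: IR factor only defined if TI constant; absorbed as 1
        pass
    if T2 is not None:
        K *= np.exp(-protocol.TE[:, None] / T2[None, :])
    if D is not None:
        b_ms = protocol.b * B_TO_MS_PER_UM2
        K *= np.exp(-b_ms[:, None] * D[None, :])
    return Kernel(matrix=K, protocol=protocol, grid=grid)


def simulate_signals(kernel: Kernel, spectra: np.ndarray) -> np.ndarray:
    """Noise-free signals from spectral amplitudes: M = F K^T per voxel.

    Parameters
    ----------
    kernel : Kernel
    spectra : ndarray (..., Q)
        Non-negative spectral amplitudes; any leading voxel dimensions.

    Returns
    -------
    ndarray (..., P)
    """
    spectra = np.asarray(spectra, dtype=float)
    if spectra.shape[-1] != kernel.Q:
        raise ValueError(
            f"spectra last dimension {spectra.shape[-1]} != kernel Q {kernel.Q}"
        )
    return spectra @ kernel.matrix.T
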