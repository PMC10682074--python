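"""Voxel-grid containers: measured signals and spectral amplitude fields."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .protocol import AcquisitionProtocol, SpectralGrid

__all__ = ["SignalVolume", "SpectrumField"]


@dataclass
class SignalVolume:
    """Real-valued signals on a voxel grid.

    Attributes
    ----------
    data : ndarray (nx, ny, nz, P)
        Per-voxel signal vectors; background voxels are zero.
    mask : ndarray (nx, ny, nz) of bool
        Brain mask; operations touch only masked voxels.
    protocol : AcquisitionProtocol
        The P contrasts, in data order.
    polarity_corrected, powder_averaged, normalized : bool
        Processing-state flags.
    """

    data: np.ndarray
    mask: np.ndarray
    protocol: AcquisitionProtocol
    polarity_corrected: bool = False
    powder_averaged: bool = False
    normalized: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (nx, ny, nz, P)")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape does not match data")
        if self.data.shape[3] != self.protocol.P:
            raise ValueError(
                f"data has {self.data.shape[3]} contrasts but protocol has "
                f"{self.protocol.P}"
            )

    @property
    def shape(self):
        return self.data.shape[:3]

    @property
    def P(self) -> int:
        return self.data.shape[3]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def masked(self) -> np.ndarray:
        """Signals of masked voxels as an (N, P) array (C-order of the mask)."""
        return self.data[self.mask]

    def with_masked(self, values: np.ndarray, **flag_updates) -> "SignalVolume":
        """Copy with masked voxel signals replaced by *values* (N, P)."""
        data = np.zeros_like(self.data)
        data[self.mask] = values
        return replace(self, data=data, **flag_updates)

    def copy(self) -> "SignalVolume":
        return replace(self, data=self.data.copy(), mask=self.mask.copy())


@dataclass
class SpectrumField:
    """Non-negative spectral amplitudes on a voxel grid.

    ``data[x, y, z]`` is the length-Q amplitude vector of a voxel, laid out
    in the grid's row-major component order.
    """

    data: np.ndarray
    mask: np.ndarray
    grid: SpectralGrid

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (nx, ny, nz, Q)")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape does not match data")
        if self.data.shape[3] != self.grid.Q:
            raise ValueError(
                f"data has {self.data.shape[3]} components but grid has {self.grid.Q}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("spectral amplitudes must be finite")

    @property
    def shape(self):
        return self.data.shape[:3]

    @property
    def Q(self) -> int:
        return self.data.shape[3]

    def masked(self) -> np.ndarray:
        return self.data[self.mask]

    def with_masked(self, values: np.ndarray) -> "SpectrumField":
        data = np.zeros_like(self.data)
        data[self.mask] = values
        return SpectrumField(data=data, mask=self.mask.copy(), grid=self.grid)

    def copy(self) -> "SpectrumField":
        return SpectrumField(data=self.data.copy(), mask=self.mask.copy(), grid=self.grid)
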