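"""Acquisition protocols and spectral grids for DW-IR-SE correlation MRI.

A DW-IR-SE (diffusion-weighted inversion-recovery spin-echo) measurement is a
list of *contrasts*, each defined by an inversion time TI (ms), an echo time
TE (ms) and a diffusion weighting b (s mm^-2), acquired at a common repetition
time TR (ms).  Multidimensional protocols vary two of the three encoding
parameters on an 8 x 8 Cartesian product, giving P = 64 unique contrasts;
diffusion-weighted shells additionally sample several gradient directions.

The non-parametric spectral inversion discretizes candidate tissue components
on linearly spaced grids of T1 (ms), T2 (ms) and diffusivity D (um^2 ms^-1).
The default grids use 60 points per axis over T1 in [50, 3000] ms, T2 in
[5, 300] ms and D in [0.05, 3] um^2 ms^-1, so a 1D grid has Q = 60 candidate
components and a 2D correlation grid has Q = 60 * 60 = 3600.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AcquisitionProtocol",
    "AxisSpec",
    "SpectralGrid",
    "make_protocol_preset",
    "build_grid",
    "default_axis",
    "DEFAULT_AXIS_RANGES",
    "DEFAULT_AXIS_POINTS",
]

#: Default spectral ranges per tissue axis: (min, max) in ms for T1/T2 and
#: um^2 ms^-1 for D.
DEFAULT_AXIS_RANGES: dict[str, tuple[float, float]] = {
    "T1": (50.0, 3000.0),
    "T2": (5.0, 300.0),
    "D": (0.05, 3.0),
}

#: Default number of grid points per axis.
DEFAULT_AXIS_POINTS = 60

_TI_LIST = (50.0, 85.0, 143.0, 243.0, 412.0, 697.0, 1181.0, 2000.0)
_TE_LIST_T1T2 = (4.5, 7.5, 12.0, 20.0, 33.0, 55.0, 91.0, 150.0)
_TE_LIST_T2D = (21.0, 28.0, 37.0, 49.0, 65.0, 86.0, 113.0, 150.0)
_B_LIST = (0.0, 50.0, 100.0, 200.0, 350.0, 550.0, 750.0, 1000.0)
_NDIR_DW = (5, 6, 6, 6, 7, 8, 10, 12)  # nominal counts per ascending b-shell


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Ordered set of DW-IR-SE contrasts.

    Parameters
    ----------
    TI : ndarray of shape (P,)
        Inversion times in ms.  ``nan`` marks a pure spin-echo contrast with
        no inversion pulse (the inversion-recovery factor is identically 1).
    TE : ndarray of shape (P,)
        Echo times in ms (strictly positive).
    b : ndarray of shape (P,)
        Diffusion weightings in s mm^-2 (non-negative).
    n_directions : ndarray of shape (P,) of int
        Number of diffusion gradient directions per contrast; 1 for b = 0.
    TR : float
        Repetition time in ms.
    name : str
        Protocol label, e.g. ``"t1t2"`` or ``"custom"``.
    """

    TI: np.ndarray
    TE: np.ndarray
    b: np.ndarray
    n_directions: np.ndarray
    TR: float
    name: str = "custom"

    def __post_init__(self):
        object.__setattr__(self, "TI", np.asarray(self.TI, dtype=float))
        object.__setattr__(self, "TE", np.asarray(self.TE, dtype=float))
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float))
        object.__setattr__(
            self, "n_directions", np.asarray(self.n_directions, dtype=int)
        )
        P = self.TI.shape[0]
        if P < 1:
            raise ValueError("protocol needs at least one contrast")
        for arr, nm in ((self.TE, "TE"), (self.b, "b"), (self.n_directions, "n_directions")):
            if arr.shape != (P,):
                raise ValueError(f"{nm} must have shape ({P},)")
        if np.any(self.TE <= 0):
            raise ValueError("TE must be positive")
        if np.any(self.b < 0):
            raise ValueError("b must be non-negative")
        ti = self.TI[np.isfinite(self.TI)]
        if np.any(ti < 0):
            raise ValueError("TI must be non-negative")
        if ti.size and self.TR <= ti.max():
            raise ValueError("TR must exceed the largest TI")
        if self.TR <= 0:
            raise ValueError("TR must be positive")
        if np.any(self.n_directions < 1):
            raise ValueError("n_directions must be >= 1")
        if np.any((self.b == 0) & (self.n_directions != 1)):
            raise ValueError("b = 0 contrasts must have exactly one direction")

    # -- basic queries -----------------------------------------------------

    @property
    def P(self) -> int:
        """Number of contrasts."""
        return self.TI.shape[0]

    @property
    def has_inversion(self) -> bool:
        return bool(np.any(np.isfinite(self.TI)))

    @property
    def total_volumes(self) -> int:
        """Total number of acquired volumes including diffusion directions."""
        return int(self.n_directions.sum())

    def parameter(self, axis: str) -> np.ndarray:
        """Scan parameter array encoding a tissue axis ('T1'|'T2'|'D')."""
        return {"T1": self.TI, "T2": self.TE, "D": self.b}[axis]

    def varied_axes(self) -> list[str]:
        """Tissue axes whose encoding scan parameter takes > 1 value."""
        out = []
        for axis in ("T1", "T2", "D"):
            vals = self.parameter(axis)
            vals = vals[np.isfinite(vals)]
            if vals.size and np.unique(vals).size > 1:
                out.append(axis)
        return out

    # -- serialization -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(self.P),
                "TI_ms": self.TI,
                "TE_ms": self.TE,
                "b_smm2": self.b,
                "n_dirs": self.n_directions,
            }
        )

    def to_table(self, path=None) -> str:
        """Delimited text table (TSV); written to *path* if given."""
        text = self.to_frame().to_csv(sep="\t", index=False, na_rep="nan")
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "TR_ms": float(self.TR),
            "contrasts": [
                {
                    "TI_ms": None if not np.isfinite(ti) else float(ti),
                    "TE_ms": float(te),
                    "b_smm2": float(b),
                    "n_directions": int(nd),
                }
                for ti, te, b, nd in zip(self.TI, self.TE, self.b, self.n_directions)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        cs = d["contrasts"]
        TI = np.array([np.nan if c["TI_ms"] is None else c["TI_ms"] for c in cs])
        return cls(
            TI=TI,
            TE=np.array([c["TE_ms"] for c in cs]),
            b=np.array([c["b_smm2"] for c in cs]),
            n_directions=np.array([c["n_directions"] for c in cs]),
            TR=d["TR_ms"],
            name=d.get("name", "custom"),
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "AcquisitionProtocol":
        if hasattr(source, "read"):
            d = yaml.safe_load(source)
        else:
            try:
                with open(source) as fh:
                    d = yaml.safe_load(fh)
            except (OSError, ValueError):
                d = yaml.safe_load(io.StringIO(str(source)))
        return cls.from_dict(d)

    def subset(self, idx, name: str | None = None) -> "AcquisitionProtocol":
        idx = np.asarray(idx)
        return AcquisitionProtocol(
            TI=self.TI[idx],
            TE=self.TE[idx],
            b=self.b[idx],
            n_directions=self.n_directions[idx],
            TR=self.TR,
            name=name or f"{self.name}-subset",
        )


def make_protocol_preset(name: str) -> AcquisitionProtocol:
    """Return one of the three 8 x 8 DW-IR-SE product protocols.

    ``t1t2``
        TI x TE product (64 contrasts), b = 0, TR = 20 s; TE from 4.5 ms.
    ``t1d``
        TI x b product, TE = 21 ms, TR = 5 s; 5..12 directions by shell.
    ``t2d``
        TE x b product, no inversion, TR = 5 s; same diffusion shells.

    The product enumerates the first-listed parameter slowest (row-major), so
    e.g. for ``t1t2`` the first 8 contrasts share TI = 50 ms.
    """
    if name == "t1t2":
        TI, TE = np.meshgrid(_TI_LIST, _TE_LIST_T1T2, indexing="ij")
        P = TI.size
        return AcquisitionProtocol(
            TI=TI.ravel(),
            TE=TE.ravel(),
            b=np.zeros(P),
            n_directions=np.ones(P, dtype=int),
            TR=20000.0,
            name="t1t2",
        )
    if name == "t1d":
        TI, b = np.meshgrid(_TI_LIST, _B_LIST, indexing="ij")
        ndir = np.array([_dirs_for_b(x) for x in b.ravel()])
        return AcquisitionProtocol(
            TI=TI.ravel(),
            TE=np.full(TI.size, 21.0),
            b=b.ravel(),
            n_directions=ndir,
            TR=5000.0,
            name="t1d",
        )
    if name == "t2d":
        TE, b = np.meshgrid(_TE_LIST_T2D, _B_LIST, indexing="ij")
        ndir = np.array([_dirs_for_b(x) for x in b.ravel()])
        return AcquisitionProtocol(
            TI=np.full(TE.size, np.nan),
            TE=TE.ravel(),
            b=b.ravel(),
            n_directions=ndir,
            TR=5000.0,
            name="t2d",
        )
    raise ValueError(f"unknown protocol preset {name!r}; choose t1t2, t1d or t2d")


def _dirs_for_b(b: float) -> int:
    # nominal scheme lists a count for every shell, but directions are
    # meaningless without diffusion weighting: the b=0 volume is acquired once
    counts = dict(zip(_B_LIST, _NDIR_DW))
    return 1 if b == 0 else counts[b]


@dataclass(frozen=True)
class AxisSpec:
    """One spectral axis: linearly spaced values over a closed interval."""

    name: str  # 'T1' | 'T2' | 'D'
    vmin: float
    vmax: float
    n: int = DEFAULT_AXIS_POINTS

    def __post_init__(self):
        if self.name not in ("T1", "T2", "D"):
            raise ValueError(f"unknown axis {self.name!r}")
        if self.name in ("T2", "D") and self.vmin <= 0:
            raise ValueError(f"{self.name} axis requires positive values")
        if self.name == "T1" and self.vmin <= 0:
            raise ValueError("T1 axis requires positive values")
        if not self.vmin < self.vmax:
            raise ValueError("axis minimum must be below maximum")
        if self.n < 2:
            raise ValueError("axis needs at least 2 points")

    @property
    def values(self) -> np.ndarray:
        return np.linspace(self.vmin, self.vmax, self.n)


def default_axis(name: str, n: int = DEFAULT_AXIS_POINTS) -> AxisSpec:
    lo, hi = DEFAULT_AXIS_RANGES[name]
    return AxisSpec(name, lo, hi, n)


@dataclass(frozen=True)
class SpectralGrid:
    """Cartesian grid of candidate tissue components (1 or 2 axes).

    Components are enumerated in row-major order: the *first* axis varies
    slowest.  For a 2D grid with axes (a1, a2) the flat component index is
    ``q = i1 * n2 + i2``.  This enumeration order is fixed; the forward
    kernel, the marginal projections and the compartment threshold boxes all
    assume it.
    """

    axes: tuple[AxisSpec, ...]

    def __post_init__(self):
        if not 1 <= len(self.axes) <= 2:
            raise ValueError("grid must have 1 or 2 axes")
        names = [a.name for a in self.axes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate grid axes")
        object.__setattr__(self, "axes", tuple(self.axes))

    @property
    def ndim(self) -> int:
        return len(self.axes)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(a.n for a in self.axes)

    @property
    def Q(self) -> int:
        return int(np.prod(self.shape))

    @property
    def axis_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.axes)

    def axis(self, name: str) -> AxisSpec:
        for a in self.axes:
            if a.name == name:
                return a
        raise KeyError(f"grid has no axis {name!r}")

    def axis_values(self, name: str) -> np.ndarray:
        return self.axis(name).values

    def component_values(self, name: str) -> np.ndarray:
        """Per-component value of axis *name*, length Q, row-major order."""
        i = self.axis_names.index(name)
        vals = self.axes[i].values
        if self.ndim == 1:
            return vals
        if i == 0:
            return np.repeat(vals, self.axes[1].n)
        return np.tile(vals, self.axes[0].n)

    def flat_index(self, *indices: int) -> int:
        return int(np.ravel_multi_index(indices, self.shape))

    def nearest_index(self, **values: float) -> int:
        """Flat index of the grid component nearest to the given axis values."""
        idx = []
        for a in self.axes:
            if a.name not in values:
                raise KeyError(f"missing value for axis {a.name}")
            idx.append(int(np.argmin(np.abs(a.values - values[a.name]))))
        return self.flat_index(*idx)

    def to_dict(self) -> dict:
        return {
            "axes": [
                {"name": a.name, "min": a.vmin, "max": a.vmax, "n": a.n}
                for a in self.axes
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpectralGrid":
        return cls(
            axes=tuple(
                AxisSpec(a["name"], a["min"], a["max"], a["n"]) for a in d["axes"]
            )
        )


def build_grid(axes) -> SpectralGrid:
    """Build a spectral grid from axis specs.

    Parameters
    ----------
    axes : sequence
        Each entry either an :class:`AxisSpec`, an axis name (uses the
        default range and 60 points) or a ``(name, min, max, n)`` tuple.
    """
    specs = []
    for a in axes:
        if isinstance(a, AxisSpec):
            specs.append(a)
        elif isinstance(a, str):
            specs.append(default_axis(a))
        else:
            specs.append(AxisSpec(*a))
    return SpectralGrid(axes=tuple(specs))
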