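"""Digital brain phantom for DW-IR-SE correlation MRI.

Generates ground-truth spectral fields and noisy multidimensional data sets
with the spectral structure observed in healthy brain: three water pools per
tissue -- myelin water (short T1/T2, low diffusivity), combined intra- and
extra-cellular water (intermediate), and CSF (long T1/T2, free diffusion).

Default compartment locations are the midpoints of the peak ranges seen in
vivo: myelin water at (T1 = 50 ms, T2 = 30 ms, D = 0.4 um^2 ms^-1), IC/EC at
(T1 = 1000 ms, T2 = 70 ms, D = 0.8 um^2 ms^-1), CSF at (T1 = 3000 ms,
T2 = 300 ms, D = 3 um^2 ms^-1).  The default geometry is a 48 x 48 single
slice of concentric regions (CSF core, GM ring, WM ring) with myelin water
fractions of 14% in WM, 6% in GM and 0% in CSF; a 156 x 156 "full-scale"
geometry is available.

Noise model: zero-mean Gaussian with standard deviation M0 / SNR added to
the signed per-direction signals, followed by the absolute value, emulating
magnitude data whose inversion-recovery polarity is lost (the default SNR of
100 is a realistic amplitude SNR for such acquisitions).  Signed-Gaussian
and noiseless variants are available for solver-level tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kernel import B_TO_MS_PER_UM2, ir_factor
from .protocol import (
    DEFAULT_AXIS_POINTS,
    DEFAULT_AXIS_RANGES,
    AcquisitionProtocol,
    SpectralGrid,
    default_axis,
)
from .volumes import SpectrumField

__all__ = [
    "Compartment",
    "RegionSpec",
    "PhantomSpec",
    "RawDataset",
    "default_phantom",
    "make_phantom",
    "simulate_dataset",
    "shell_directions",
]


@dataclass(frozen=True)
class Compartment:
    """A single water pool: signal fraction and (T1, T2, D) location.

    ``d_delta`` is an optional axially symmetric diffusion anisotropy: with
    fiber axis along z, the per-direction diffusivity is
    ``D * (1 + d_delta * (3 cos^2(theta) - 1))`` where theta is the angle
    between gradient direction and fiber; the orientational mean is D.
    """

    name: str
    fraction: float
    T1: float
    T2: float
    D: float
    d_delta: float = 0.0

    def __post_init__(self):
        if self.fraction < 0:
            raise ValueError("fraction must be non-negative")
        for v, nm in ((self.T1, "T1"), (self.T2, "T2"), (self.D, "D")):
            if v <= 0:
                raise ValueError(f"{nm} must be positive")


@dataclass(frozen=True)
class RegionSpec:
    """A tissue region: compartment mixture plus baseline amplitude M0."""

    name: str
    mixture: tuple[Compartment, ...]
    M0: float = 1.0

    def __post_init__(self):
        total = sum(c.fraction for c in self.mixture)
        if self.mixture and not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"region {self.name!r} fractions sum to {total}, not 1")
        if self.M0 <= 0:
            raise ValueError("M0 must be positive")


@dataclass
class PhantomSpec:
    """Geometry + tissue composition + noise level of a digital phantom."""

    shape: tuple[int, int, int]
    masks: dict  # region name -> bool ndarray of `shape`
    regions: dict  # region name -> RegionSpec
    snr: float | None = 100.0
    seed: int = 0

    def __post_init__(self):
        occupancy = np.zeros(self.shape, dtype=int)
        for name, m in self.masks.items():
            m = np.asarray(m, dtype=bool)
            if m.shape != tuple(self.shape):
                raise ValueError(f"mask {name!r} has wrong shape")
            self.masks[name] = m
            occupancy += m
            if name not in self.regions:
                raise ValueError(f"mask {name!r} has no region definition")
        if np.any(occupancy > 1):
            raise ValueError("region masks must be disjoint")
        for name, reg in self.regions.items():
            for c in reg.mixture:
                for axis, v in (("T1", c.T1), ("T2", c.T2), ("D", c.D)):
                    lo, hi = DEFAULT_AXIS_RANGES[axis]
                    if not lo <= v <= hi:
                        raise ValueError(
                            f"component {c.name!r} of region {name!r}: "
                            f"{axis} = {v} outside grid range [{lo}, {hi}]"
                        )

    @property
    def brain_mask(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        for m in self.masks.values():
            out |= m
        return out

    def ground_truth_fractions(self) -> pd.DataFrame:
        """Per-region spectral signal fractions by compartment name."""
        rows = []
        for name, reg in self.regions.items():
            row = {"region": name}
            for c in reg.mixture:
                row[c.name] = row.get(c.name, 0.0) + c.fraction
            rows.append(row)
        return pd.DataFrame(rows).fillna(0.0)


def _default_regions(mwf_wm=0.14, mwf_gm=0.06) -> dict:
    mw = dict(T1=50.0, T2=30.0, D=0.4)
    icec = dict(T1=1000.0, T2=70.0, D=0.8)
    csf = dict(T1=3000.0, T2=300.0, D=3.0)
    return {
        "WM": RegionSpec(
            "WM",
            (
                Compartment("MW", mwf_wm, **mw),
                Compartment("IC/EC", 1.0 - mwf_wm, **icec),
            ),
        ),
        "GM": RegionSpec(
            "GM",
            (
                Compartment("MW", mwf_gm, **mw),
                Compartment("IC/EC", 1.0 - mwf_gm, **icec),
            ),
        ),
        "CSF": RegionSpec("CSF", (Compartment("CSF", 1.0, **csf),)),
    }


def default_phantom(
    size: int = 48, snr: float | None = 100.0, seed: int = 0, full_scale: bool = False
) -> PhantomSpec:
    """Concentric-annuli phantom: CSF core, GM ring, WM ring, background.

    With ``full_scale=True`` the in-plane matrix is 156 x 156 (the scanner
    matrix size); otherwise ``size`` x ``size`` (default 48).
    """
    n = 156 if full_scale else size
    shape = (n, n, 1)
    c = (n - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    r = np.hypot(xx - c, yy - c)[..., None]  # add z axis
    scale = n / 48.0
    # CSF core ~ ventricle size; GM ring wide enough to stand for cortical
    # plus deep gray matter (thin structures suffer boundary smoothing from
    # the spatially regularized solvers, as tissue interfaces do in vivo)
    r_csf, r_gm, r_wm = 6.0 * scale, 14.0 * scale, 21.0 * scale
    masks = {
        "CSF": r < r_csf,
        "GM": (r >= r_csf) & (r < r_gm),
        "WM": (r >= r_gm) & (r < r_wm),
    }
    return PhantomSpec(
        shape=shape, masks=masks, regions=_default_regions(), snr=snr, seed=seed
    )


def _snap(value: float, values: np.ndarray) -> float:
    return float(values[np.argmin(np.abs(values - value))])


def make_phantom(
    spec: PhantomSpec, grid: SpectralGrid | None = None
) -> tuple[SpectrumField, dict]:
    """Ground-truth spectral field with each component snapped to the grid.

    Per voxel the spectrum holds the region's compartment fractions at the
    grid cells nearest to the true (T1, T2, D); background voxels are zero.
    Returns ``(field, masks)``.
    """
    if grid is None:
        grid = SpectralGrid(axes=(default_axis("T1"), default_axis("T2")))
    mask = spec.brain_mask
    data = np.zeros(spec.shape + (grid.Q,), dtype=float)
    for name, m in spec.masks.items():
        reg = spec.regions[name]
        vec = np.zeros(grid.Q)
        for comp in reg.mixture:
            values = {"T1": comp.T1, "T2": comp.T2, "D": comp.D}
            q = grid.nearest_index(**{a: values[a] for a in grid.axis_names})
            vec[q] += comp.fraction
        data[m] = vec
    return SpectrumField(data=data, mask=mask, grid=grid), dict(spec.masks)


def shell_directions(n: int, seed_axis: int = 0) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors (Fibonacci sphere), (n, 3)."""
    if n == 1:
        return np.array([[0.0, 0.0, 1.0]])
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    golden = np.pi * (1 + 5**0.5)
    theta = golden * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


@dataclass
class RawDataset:
    """Per-direction raw volumes plus the table describing each volume.

    ``data`` has shape (nx, ny, nz, V) with V = sum of per-contrast direction
    counts; ``volumes`` is a DataFrame with columns (volume, contrast, TI_ms,
    TE_ms, b_smm2, direction) mapping the 4th-axis index to its contrast.
    """

    data: np.ndarray
    volumes: pd.DataFrame
    protocol: AcquisitionProtocol
    mask: np.ndarray


def _snapped_components(spec: PhantomSpec) -> dict:
    """Region -> list of (fraction, T1, T2, D, d_delta) snapped to the
    default 60-point axes, so simulated data are exactly on-grid."""
    axes = {a: default_axis(a).values for a in ("T1", "T2", "D")}
    out = {}
    for name, reg in spec.regions.items():
        comps = []
        for c in reg.mixture:
            comps.append(
                (
                    c.fraction,
                    _snap(c.T1, axes["T1"]),
                    _snap(c.T2, axes["T2"]),
                    _snap(c.D, axes["D"]),
                    c.d_delta,
                )
            )
        out[name] = comps
    return out


def simulate_dataset(
    spec: PhantomSpec,
    protocol: AcquisitionProtocol,
    snr: float | None = None,
    seed: int | None = None,
    noise: str = "magnitude",
) -> RawDataset:
    """Simulate raw per-direction DW-IR-SE data from a phantom.

    Each voxel's signed signal per contrast and direction is the forward
    model evaluated at the region's (grid-snapped) compartments, scaled by
    the region M0.  Gaussian noise of standard deviation ``M0_ref / snr``
    (M0_ref = largest region M0) is added to the signed signals; with
    ``noise="magnitude"`` (default) the absolute value is then taken,
    discarding inversion-recovery polarity.  ``noise="signed"`` keeps the
    signs; ``snr=None`` (or the spec default) with ``noise=None`` gives
    noiseless signed data.

    Deterministic given ``seed`` (defaults to ``spec.seed``).
    """
    if snr is None:
        snr = spec.snr
    if seed is None:
        seed = spec.seed
    if snr is not None and snr <= 0:
        raise ValueError("snr must be positive")

    # volume table
    rows = []
    v = 0
    for p in range(protocol.P):
        for d in range(int(protocol.n_directions[p])):
            rows.append(
                {
                    "volume": v,
                    "contrast": p,
                    "TI_ms": protocol.TI[p],
                    "TE_ms": protocol.TE[p],
                    "b_smm2": protocol.b[p],
                    "direction": d,
                }
            )
            v += 1
    table = pd.DataFrame(rows)
    V = v

    dirs_by_count = {
        int(n): shell_directions(int(n)) for n in np.unique(protocol.n_directions)
    }
    fiber = np.array([0.0, 0.0, 1.0])

    data = np.zeros(spec.shape + (V,), dtype=float)
    comps = _snapped_components(spec)
    for name, m in spec.masks.items():
        sig = np.zeros(V)
        for frac, T1, T2, D, d_delta in comps[name]:
            amp = spec.regions[name].M0 * frac
            irf = ir_factor(protocol.TI, protocol.TR, T1)  # (P,)
            t2f = np.exp(-protocol.TE / T2)
            for _, row in table.iterrows():
                p = int(row["contrast"])
                b_ms = protocol.b[p] * B_TO_MS_PER_UM2
                if d_delta != 0.0 and protocol.b[p] > 0:
                    g = dirs_by_count[int(protocol.n_directions[p])][int(row["direction"])]
                    cos2 = float(np.dot(g, fiber)) ** 2
                    D_eff = D * (1.0 + d_delta * (3.0 * cos2 - 1.0))
                else:
                    D_eff = D
                sig[int(row["volume"])] += amp * irf[p] * t2f[p] * np.exp(-b_ms * D_eff)
        data[m] = sig

    mask = spec.brain_mask
    if snr is not None and noise is not None:
        rng = np.random.default_rng(seed)
        m0_ref = max(reg.M0 for reg in spec.regions.values())
        sigma = m0_ref / snr
        data = data + rng.normal(0.0, sigma, size=data.shape)
        if noise == "magnitude":
            data = np.abs(data)
        elif noise != "signed":
            raise ValueError("noise must be 'magnitude', 'signed' or None")

    return RawDataset(data=data, volumes=table, protocol=protocol, mask=mask)
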