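"""Compartment delineation, signal-fraction maps, histograms, fit errors.

Spectral peaks are assigned to three water pools by manually set threshold
boxes in (T1, T2, D) space: myelin water (MW), combined intra/extra-cellular
water (IC/EC) and CSF.  Per voxel, a compartment's raw signal fraction is the
sum of spectral amplitude inside its box (discrete integration on the
uniform grid, so the constant cell size cancels in the normalization);
spurious amplitude outside all boxes is ignored.  The three fractions are
then renormalized so that MWF + f_IC/EC + f_CSF = 1.

Default boxes (closed intervals, each upper edge owned by the lower box):
MW T1 in [50, 300] ms, T2 in [5, 47] ms, D in [0.05, 0.6] um^2/ms; IC/EC up
to T1 = 2000 ms, T2 = 120 ms, D = 1.3 um^2/ms; CSF the remainder of the
grid.  These contain the in vivo peak ranges (myelin water T2 ~ 20-45 ms,
IC/EC T1 ~ 700-1400 ms, ...) well inside their boxes and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .kernel import Kernel
from .volumes import SignalVolume, SpectrumField

__all__ = [
    "CompartmentDefinition",
    "FractionMaps",
    "default_compartments",
    "slice_average_spectrum",
    "integrate_compartments",
    "mwf_histogram_fit",
    "rmse_map",
    "tissue_summary",
]

_DEFAULT_EDGES = {
    # axis -> (MW upper, IC/EC upper); lower/upper grid bounds close the rest
    "T1": (300.0, 2000.0),
    "T2": (47.0, 120.0),
    "D": (0.6, 1.3),
}


@dataclass(frozen=True)
class CompartmentDefinition:
    """A threshold box in spectral space.

    ``intervals`` maps axis name to (lo, hi).  The interval is half-open
    (lo, hi] unless ``lo_closed`` is set (used for the lowest box so the
    grid minimum belongs to it); shared edges therefore belong to exactly
    one box.
    """

    name: str
    intervals: dict
    lo_closed: bool = False

    def membership(self, grid) -> np.ndarray:
        """Boolean mask over the grid's Q components (row-major order)."""
        inside = np.ones(grid.Q, dtype=bool)
        for axis in grid.axis_names:
            if axis not in self.intervals:
                continue
            lo, hi = self.intervals[axis]
            v = grid.component_values(axis)
            if self.lo_closed:
                inside &= (v >= lo) & (v <= hi)
            else:
                inside &= (v > lo) & (v <= hi)
        return inside


def default_compartments(grid) -> list[CompartmentDefinition]:
    """MW / IC/EC / CSF boxes restricted to the axes present on *grid*."""
    axes = grid.axis_names
    lo = {a: grid.axis(a).vmin for a in axes}
    hi = {a: grid.axis(a).vmax for a in axes}
    mw, icec, csf = {}, {}, {}
    for a in axes:
        e_mw, e_ic = _DEFAULT_EDGES[a]
        mw[a] = (lo[a], e_mw)
        icec[a] = (e_mw, e_ic)
        csf[a] = (e_ic, hi[a])
    return [
        CompartmentDefinition("MW", mw, lo_closed=True),
        CompartmentDefinition("IC/EC", icec),
        CompartmentDefinition("CSF", csf),
    ]


@dataclass
class FractionMaps:
    """Per-voxel normalized compartmental signal fractions."""

    mwf: np.ndarray
    f_icec: np.ndarray
    f_csf: np.ndarray
    mask: np.ndarray
    flagged: np.ndarray  # masked voxels with zero in-box spectral mass

    def as_dict(self) -> dict:
        return {"MW": self.mwf, "IC/EC": self.f_icec, "CSF": self.f_csf}

    @property
    def valid(self) -> np.ndarray:
        return self.mask & ~self.flagged


def slice_average_spectrum(F: SpectrumField, z: int) -> np.ndarray:
    """Arithmetic mean spectrum over the masked voxels of slice *z*."""
    sl_mask = F.mask[:, :, z]
    if not sl_mask.any():
        raise ValueError(f"slice {z} contains no masked voxels")
    return F.data[:, :, z][sl_mask].mean(axis=0)


def integrate_compartments(
    F: SpectrumField, defs: list[CompartmentDefinition] | None = None
) -> FractionMaps:
    """Thresholded integration of the voxel-wise spectra.

    Amplitude outside every box is discarded; the three in-box sums are
    normalized to 1.  Voxels whose total in-box mass is zero are flagged
    (fractions set to nan).
    """
    defs = defs if defs is not None else default_compartments(F.grid)
    members = [d.membership(F.grid) for d in defs]
    overlap = np.sum(members, axis=0)
    if np.any(overlap > 1):
        raise ValueError("compartment boxes overlap on the grid")

    A = F.masked()  # (N, Q)
    raw = np.stack([A[:, m].sum(axis=1) for m in members], axis=1)  # (N, 3)
    total = raw.sum(axis=1)
    ok = total > 0
    fr = np.full_like(raw, np.nan)
    fr[ok] = raw[ok] / total[ok, None]

    shape = F.shape
    maps = {}
    for j, d in enumerate(defs):
        vol = np.full(shape, np.nan)
        vol[F.mask] = fr[:, j]
        maps[d.name] = vol
    flagged = np.zeros(shape, dtype=bool)
    flagged[F.mask] = ~ok
    by_name = {d.name: maps[d.name] for d in defs}
    return FractionMaps(
        mwf=by_name.get("MW", np.zeros(shape)),
        f_icec=by_name.get("IC/EC", np.zeros(shape)),
        f_csf=by_name.get("CSF", np.zeros(shape)),
        mask=F.mask.copy(),
        flagged=flagged,
    )


def _gauss_mixture(x, *params):
    out = np.zeros_like(x)
    for k in range(len(params) // 3):
        a, mu, sd = params[3 * k : 3 * k + 3]
        out = out + a * np.exp(-0.5 * ((x - mu) / sd) ** 2)
    return out


def mwf_histogram_fit(
    mwf_map: np.ndarray,
    mask: np.ndarray,
    bin_width: float = 0.002,
    n_components: int = 2,
) -> pd.DataFrame:
    """Histogram the MWF values in *mask* and fit a sum of Gaussians.

    The histogram uses the given bin width (default 0.2 percentage points);
    1-3 Gaussian components are fitted to the bin counts by nonlinear least
    squares.  Returns a DataFrame (mean, sd, amplitude) sorted by mean.
    """
    if not 1 <= n_components <= 3:
        raise ValueError("n_components must be 1, 2 or 3")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    vals = np.asarray(mwf_map)[np.asarray(mask, bool)]
    vals = vals[np.isfinite(vals)]
    if vals.size < 3 * n_components:
        raise ValueError("fewer voxels than fit parameters")

    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = np.ceil(vals.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    # moment/quantile-based initialization: split the sample into
    # n_components quantile groups
    qs = np.quantile(vals, np.linspace(0, 1, n_components + 1))
    p0 = []
    bounds_lo, bounds_hi = [], []
    for k in range(n_components):
        grp = vals[(vals >= qs[k]) & (vals <= qs[k + 1])]
        mu = float(np.mean(grp)) if grp.size else float(np.mean(vals))
        sd = max(float(np.std(grp)), bin_width / 2)
        amp = max(float(counts.max()) / n_components, 1.0)
        p0 += [amp, mu, sd]
        bounds_lo += [0.0, lo - bin_width, bin_width / 10]
        bounds_hi += [np.inf, hi + bin_width, hi - lo + bin_width]
    try:
        popt, _ = curve_fit(
            _gauss_mixture,
            centers,
            counts.astype(float),
            p0=p0,
            bounds=(bounds_lo, bounds_hi),
            maxfev=20000,
        )
    except RuntimeError:
        popt = np.asarray(p0, dtype=float)
    comps = sorted(
        [(popt[3 * k + 1], popt[3 * k + 2], popt[3 * k]) for k in range(n_components)]
    )
    return pd.DataFrame(comps, columns=["mean", "sd", "amplitude"])


def rmse_map(signals: SignalVolume, kernel: Kernel, F: SpectrumField) -> np.ndarray:
    """Per-voxel root-mean-square error of the predicted signals.

    RMSE_i = sqrt(||M_i - K F_i||^2 / P); nan outside the mask.
    """
    if kernel.P != signals.P:
        raise ValueError("kernel and signals disagree on contrast count")
    if kernel.Q != F.Q:
        raise ValueError("kernel and spectra disagree on component count")
    M = signals.masked()
    pred = F.masked() @ kernel.matrix.T
    rmse = np.sqrt(np.mean((M - pred) ** 2, axis=1))
    out = np.full(signals.shape, np.nan)
    out[signals.mask] = rmse
    return out


def tissue_summary(fractions: FractionMaps, masks: dict) -> pd.DataFrame:
    """Per-tissue MWF statistics as a delimited-text-ready table."""
    rows = []
    for name, m in masks.items():
        sel = np.asarray(m, bool) & fractions.valid
        v = fractions.mwf[sel]
        v = v[np.isfinite(v)]
        rows.append(
            {
                "tissue": name,
                "mean_mwf": float(np.mean(v)) if v.size else np.nan,
                "sd_mwf": float(np.std(v)) if v.size else np.nan,
                "median_mwf": float(np.median(v)) if v.size else np.nan,
                "n_voxels": int(v.size),
            }
        )
    return pd.DataFrame(rows)
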