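"""Figure helpers: spectra, fraction maps, MWF histograms.

Thin matplotlib wrappers used by the ``report`` CLI subcommand; every
function accepts an existing Axes or creates one, and returns the Axes.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")  # headless by default; harmless under a GUI backend
import matplotlib.pyplot as plt

from .analysis import mwf_histogram_fit, slice_average_spectrum
from .volumes import SpectrumField

__all__ = [
    "plot_spectrum_1d",
    "plot_spectrum_2d",
    "plot_map",
    "plot_mwf_histogram",
]

_AXIS_LABEL = {"T1": "T1 (ms)", "T2": "T2 (ms)", "D": "D (um^2/ms)"}


def plot_spectrum_1d(F: SpectrumField, z: int = 0, ax=None):
    """Slice-average 1D spectrum as a line plot."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    s = slice_average_spectrum(F, z)
    axis = F.grid.axes[0]
    ax.plot(axis.values, s, lw=1.5)
    ax.set_xlabel(_AXIS_LABEL[axis.name])
    ax.set_ylabel("amplitude")
    ax.set_title(f"slice-average {axis.name} spectrum")
    return ax


def plot_spectrum_2d(F: SpectrumField, z: int = 0, ax=None, cmap="viridis"):
    """Slice-average 2D correlation spectrum as an image."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    s = slice_average_spectrum(F, z).reshape(F.grid.shape)
    a1, a2 = F.grid.axes
    ax.imshow(
        s,
        origin="lower",
        aspect="auto",
        extent=(a2.vmin, a2.vmax, a1.vmin, a1.vmax),
        cmap=cmap,
    )
    ax.set_xlabel(_AXIS_LABEL[a2.name])
    ax.set_ylabel(_AXIS_LABEL[a1.name])
    ax.set_title(f"slice-average {a1.name}-{a2.name} spectrum")
    return ax


def plot_map(data: np.ndarray, z: int = 0, ax=None, cmap="viridis", title=""):
    """Scalar map (fraction or RMSE) of one slice."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(data[:, :, z].T, origin="lower", cmap=cmap)
    plt.colorbar(im, ax=ax, fraction=0.046)
    ax.set_title(title)
    ax.axis("off")
    return ax


def plot_mwf_histogram(
    mwf_map: np.ndarray,
    mask: np.ndarray,
    bin_width: float = 0.002,
    n_components: int = 2,
    ax=None,
):
    """MWF histogram (0.2 percentage-point bins) with Gaussian-fit overlay."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    vals = np.asarray(mwf_map)[np.asarray(mask, bool)]
    vals = vals[np.isfinite(vals)]
    edges = np.arange(0, max(vals.max(), bin_width) + bin_width, bin_width)
    ax.hist(vals, bins=edges, color="0.7")
    try:
        fit = mwf_histogram_fit(mwf_map, mask, bin_width, n_components)
        x = np.linspace(edges[0], edges[-1], 400)
        y = np.zeros_like(x)
        for _, row in fit.iterrows():
            y += row["amplitude"] * np.exp(-0.5 * ((x - row["mean"]) / row["sd"]) ** 2)
        ax.plot(x, y, "r-", lw=1.5)
    except (ValueError, RuntimeError):
        pass
    ax.set_xlabel("MWF")
    ax.set_ylabel("voxel count")
    return ax
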