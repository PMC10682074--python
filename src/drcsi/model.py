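"""Model/Results interface to the spectral inversion.

``SpectralModel`` bundles preprocessed signals, a spectral grid and the
forward kernel; ``fit()`` dispatches to the ADMM solver (1D grids) or the
marginal-constrained Douglas-Rachford solver (2D grids) and returns a
``SpectralFitResults`` carrying the estimated spectra, convergence
diagnostics, predicted signals, fit-error maps, compartment fraction maps
and a printable summary.

Example
-------
>>> model = SpectralModel(signals_1d, grid=build_grid(["T1"]))
>>> res = model.fit()
>>> res.fraction_maps().mwf  # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np

from .analysis import (
    default_compartments,
    integrate_compartments,
    rmse_map,
    slice_average_spectrum,
    tissue_summary,
)
from .kernel import Kernel, build_kernel, simulate_signals
from .protocol import SpectralGrid, build_grid
from .solve1d import SolverConfig1D, solve_1d_admm
from .solve2d import SolverConfig2D, solve_2d_dr
from .volumes import SignalVolume, SpectrumField

__all__ = ["SpectralModel", "SpectralFitResults"]


class SpectralModel:
    """Non-parametric spectral model M = K F, F >= 0, on a voxel grid.

    Parameters
    ----------
    signals : SignalVolume
        Conditioned signals (powder-averaged, polarity-corrected,
        L2-normalized as applicable).
    grid : SpectralGrid, optional
        Candidate-component grid; by default built from the tissue axes the
        protocol varies (60 points per axis over the default ranges).
    kernel : Kernel, optional
        Precomputed forward kernel (built on demand otherwise).
    nuisance : dict, optional
        Fixed tissue values for varied scan parameters without a grid axis.
    """

    def __init__(
        self,
        signals: SignalVolume,
        grid: SpectralGrid | None = None,
        kernel: Kernel | None = None,
        nuisance: dict | None = None,
    ):
        self.signals = signals
        if grid is None:
            axes = signals.protocol.varied_axes()
            if not axes:
                raise ValueError("protocol varies no tissue axis; supply a grid")
            grid = build_grid(axes[:2])
        self.grid = grid
        self.kernel = kernel or build_kernel(signals.protocol, grid, nuisance=nuisance)

    def fit(
        self,
        method: str | None = None,
        config=None,
        marginals: tuple[SpectrumField, SpectrumField] | None = None,
    ) -> "SpectralFitResults":
        """Estimate the spectra.

        method : 'admm' (1D, default for 1D grids) or 'dr' (2D, default for
        2D grids; requires ``marginals``, the two 1D solutions).
        """
        if method is None:
            method = "admm" if self.grid.ndim == 1 else "dr"
        if method == "admm":
            config = config or SolverConfig1D()
            field, log = solve_1d_admm(self.signals, self.kernel, config, full_output=True)
        elif method == "dr":
            if marginals is None:
                raise ValueError(
                    "the 2D solver requires marginals=(F_axis1, F_axis2), the "
                    "1D solutions along both grid axes; fit the 1D subsets first"
                )
            config = config or SolverConfig2D()
            field, log = solve_2d_dr(
                self.signals, self.kernel, marginals, config, full_output=True
            )
        else:
            raise ValueError(f"unknown method {method!r}")
        return SpectralFitResults(self, field, log, method, config)


class SpectralFitResults:
    """Fitted spectra plus diagnostics.

    Attributes
    ----------
    spectra : SpectrumField
        Estimated non-negative amplitudes per voxel.
    log : ConvergenceLog or DRLog
        Iteration history; ``converged`` / ``n_iter``.
    """

    def __init__(self, model: SpectralModel, spectra: SpectrumField, log, method, config):
        self.model = model
        self.spectra = spectra
        self.log = log
        self.method = method
        self.config = config

    @property
    def converged(self) -> bool:
        return bool(self.log.converged)

    @property
    def n_iter(self) -> int:
        return int(self.log.n_iter)

    def predict(self) -> np.ndarray:
        """Model signals K F for every masked voxel, shape (N, P)."""
        return simulate_signals(self.model.kernel, self.spectra.masked())

    def rmse_map(self) -> np.ndarray:
        """Voxel-wise RMSE of the fit against the model's own signals."""
        return rmse_map(self.model.signals, self.model.kernel, self.spectra)

    def fraction_maps(self, compartments=None):
        """Thresholded-integration signal fraction maps (MW, IC/EC, CSF)."""
        comps = compartments or default_compartments(self.spectra.grid)
        return integrate_compartments(self.spectra, comps)

    def slice_average(self, z: int = 0) -> np.ndarray:
        return slice_average_spectrum(self.spectra, z)

    def summary(self, masks: dict | None = None) -> str:
        """Printable fit report; per-tissue MWF statistics if masks given."""
        g = self.spectra.grid
        lines = [
            "Spectral inversion results",
            "==========================",
            f"method:      {self.method} "
            f"({'ADMM' if self.method == 'admm' else 'Douglas-Rachford'})",
            f"grid:        {' x '.join(a.name for a in g.axes)} "
            f"({' x '.join(str(a.n) for a in g.axes)} = {g.Q} components)",
            f"contrasts:   P = {self.model.signals.P}",
            f"voxels:      N = {self.model.signals.n_voxels}",
            f"iterations:  {self.n_iter} (converged: {self.converged})",
        ]
        if hasattr(self.config, "lambda_m"):
            lines.append(
                f"weights:     lambda_s2D = {self.config.lambda_s}, "
                f"lambda_m = {self.config.lambda_m}"
            )
        else:
            lines.append(f"weights:     lambda_s1D = {self.config.lambda_s}")
        rm = self.rmse_map()
        lines.append(f"mean RMSE:   {np.nanmean(rm):.6g}")
        if masks:
            fm = self.fraction_maps()
            tbl = tissue_summary(fm, masks)
            lines.append("")
            lines.append(tbl.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)
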