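"""Compartment integration, fraction maps, histograms, RMSE maps."""

import numpy as np
import pytest

from drcsi.analysis import (
    CompartmentDefinition,
    default_compartments,
    integrate_compartments,
    mwf_histogram_fit,
    rmse_map,
    slice_average_spectrum,
    tissue_summary,
)
from drcsi.kernel import build_kernel
from drcsi.protocol import AxisSpec, build_grid, make_protocol_preset
from drcsi.volumes import SignalVolume, SpectrumField


def _field(data, grid):
    data = np.asarray(data, float)
    mask = np.ones(data.shape[:3], bool)
    return SpectrumField(data=data, mask=mask, grid=grid)


class TestCompartmentBoxes:
    def test_default_boxes_are_disjoint_and_cover_peaks(self):
        g = build_grid(["T1", "T2"])
        defs = default_compartments(g)
        members = np.stack([d.membership(g) for d in defs])
        assert np.all(members.sum(axis=0) <= 1)
        # the in vivo peak locations fall in their boxes
        q_mw = g.nearest_index(T1=50.0, T2=30.0)
        q_ic = g.nearest_index(T1=1000.0, T2=70.0)
        q_csf = g.nearest_index(T1=3000.0, T2=300.0)
        assert members[0, q_mw] and members[1, q_ic] and members[2, q_csf]

    def test_shared_edge_belongs_to_lower_box(self):
        g = build_grid(["T1"])
        defs = default_compartments(g)
        v = g.component_values("T1")
        (q300,) = np.where(v == 300.0)
        assert defs[0].membership(g)[q300[0]]
        assert not defs[1].membership(g)[q300[0]]


class TestSliceAverage:
    def test_identical_voxels_return_that_spectrum(self):
        g = build_grid(["T1"])
        spec = np.zeros(60)
        spec[10] = 1.0
        F = _field(np.tile(spec, (3, 3, 1, 1)), g)
        np.testing.assert_allclose(slice_average_spectrum(F, 0), spec)

    def test_two_disjoint_peaks_average_to_half_height(self):
        g = build_grid(["T1"])
        data = np.zeros((2, 1, 1, 60))
        data[0, 0, 0, 5] = 1.0
        data[1, 0, 0, 50] = 1.0
        F = _field(data, g)
        s = slice_average_spectrum(F, 0)
        assert s[5] == 0.5 and s[50] == 0.5

    def test_empty_slice_raises(self):
        g = build_grid(["T1"])
        F = SpectrumField(np.zeros((2, 2, 1, 60)), np.zeros((2, 2, 1), bool), g)
        with pytest.raises(ValueError):
            slice_average_spectrum(F, 0)


class TestIntegrateCompartments:
    def test_pure_mw_spectrum_gives_unit_mwf(self):
        g = build_grid(["T1"])
        data = np.zeros((1, 1, 1, 60))
        data[0, 0, 0, :3] = [0.2, 0.5, 0.3]  # T1 = 50, 100, 150 ms, all MW
        fm = integrate_compartments(_field(data, g))
        assert fm.mwf[0, 0, 0] == pytest.approx(1.0)

    def test_out_of_box_mass_ignored_before_normalization(self):
        g = build_grid(["T1", "T2"])
        data = np.zeros((1, 1, 1, 3600))
        data[0, 0, 0, g.nearest_index(T1=50.0, T2=30.0)] = 0.14
        data[0, 0, 0, g.nearest_index(T1=1000.0, T2=70.0)] = 0.86
        # spurious mass in a region outside every box: short T1, long T2
        data[0, 0, 0, g.nearest_index(T1=50.0, T2=290.0)] = 0.05
        fm = integrate_compartments(_field(data, g))
        assert fm.mwf[0, 0, 0] == pytest.approx(0.14)
        assert fm.f_icec[0, 0, 0] == pytest.approx(0.86)

    def test_fractions_sum_to_one(self):
        g = build_grid(["T1"])
        rng = np.random.default_rng(0)
        data = rng.random((4, 4, 1, 60))
        fm = integrate_compartments(_field(data, g))
        s = fm.mwf + fm.f_icec + fm.f_csf
        np.testing.assert_allclose(s[fm.valid], 1.0, atol=1e-9)

    def test_invariant_to_global_rescaling(self):
        g = build_grid(["T1"])
        rng = np.random.default_rng(1)
        data = rng.random((3, 3, 1, 60))
        a = integrate_compartments(_field(data, g))
        b = integrate_compartments(_field(data * 123.4, g))
        np.testing.assert_allclose(a.mwf, b.mwf, atol=1e-12)

    def test_zero_spectrum_flagged(self):
        g = build_grid(["T1"])
        data = np.zeros((2, 1, 1, 60))
        data[0, 0, 0, 10] = 1.0
        fm = integrate_compartments(_field(data, g))
        assert not fm.flagged[0, 0, 0]
        assert fm.flagged[1, 0, 0]
        assert np.isnan(fm.mwf[1, 0, 0])

    def test_overlapping_boxes_rejected(self):
        g = build_grid(["T1"])
        defs = [
            CompartmentDefinition("MW", {"T1": (50.0, 400.0)}, lo_closed=True),
            CompartmentDefinition("IC/EC", {"T1": (300.0, 2000.0)}),
            CompartmentDefinition("CSF", {"T1": (2000.0, 3000.0)}),
        ]
        with pytest.raises(ValueError, match="overlap"):
            integrate_compartments(_field(np.ones((1, 1, 1, 60)), g), defs)


class TestHistogramFit:
    def test_delta_map_single_component(self):
        mwf = np.full((10, 10, 1), 0.10)
        fit = mwf_histogram_fit(mwf, np.ones((10, 10, 1), bool), n_components=1)
        assert fit["mean"].iloc[0] == pytest.approx(0.10, abs=0.002)

    def test_two_gaussian_recovery_at_reported_tissue_values(self):
        """500 GM-like draws N(0.062, 0.003^2) + 500 WM-like draws
        N(0.140, 0.017^2): recovered means within 2 sd of sample means."""
        rng = np.random.default_rng(123)
        gm = rng.normal(0.062, 0.003, 500)
        wm = rng.normal(0.140, 0.017, 500)
        mwf = np.concatenate([gm, wm]).reshape(20, 50, 1)
        fit = mwf_histogram_fit(mwf, np.ones((20, 50, 1), bool), n_components=2)
        assert fit["mean"].iloc[0] == pytest.approx(gm.mean(), abs=2 * 0.003)
        assert fit["mean"].iloc[1] == pytest.approx(wm.mean(), abs=2 * 0.017)
        assert list(fit["mean"]) == sorted(fit["mean"])

    def test_disjoint_masks_fit_independently(self):
        rng = np.random.default_rng(5)
        mwf = np.zeros((10, 10, 1))
        m1 = np.zeros_like(mwf, bool)
        m2 = np.zeros_like(mwf, bool)
        m1[:5] = True
        m2[5:] = True
        mwf[m1] = rng.normal(0.06, 0.002, m1.sum())
        mwf[m2] = rng.normal(0.14, 0.002, m2.sum())
        f1 = mwf_histogram_fit(mwf, m1, n_components=1)
        f2 = mwf_histogram_fit(mwf, m2, n_components=1)
        assert f1["mean"].iloc[0] == pytest.approx(0.06, abs=0.005)
        assert f2["mean"].iloc[0] == pytest.approx(0.14, abs=0.005)

    def test_too_few_voxels_raises(self):
        with pytest.raises(ValueError, match="fewer voxels"):
            mwf_histogram_fit(np.array([[[0.1]]]), np.ones((1, 1, 1), bool))


class TestRmseMap:
    @pytest.fixture(scope="class")
    def kernel(self):
        prot = make_protocol_preset("t1t2")
        sel = np.where(prot.TE == 4.5)[0]
        return build_kernel(prot.subset(sel), build_grid(["T1"]))

    def _sv(self, M, prot):
        return SignalVolume(
            M.reshape(1, 1, 1, -1), np.ones((1, 1, 1), bool), prot,
            polarity_corrected=True, powder_averaged=True, normalized=True,
        )

    def test_exact_fit_gives_zero(self, kernel):
        F = np.zeros((1, 1, 1, 60))
        F[0, 0, 0, 7] = 1.0
        M = kernel.matrix[:, 7]
        sv = self._sv(M, kernel.protocol)
        out = rmse_map(sv, kernel, SpectrumField(F, sv.mask, kernel.grid))
        assert out[0, 0, 0] == pytest.approx(0.0, abs=1e-14)

    def test_zero_spectrum_gives_norm_over_sqrt_p(self, kernel):
        M = np.random.default_rng(0).random(8)
        M /= np.linalg.norm(M)
        sv = self._sv(M, kernel.protocol)
        F = SpectrumField(np.zeros((1, 1, 1, 60)), sv.mask, kernel.grid)
        out = rmse_map(sv, kernel, F)
        assert out[0, 0, 0] == pytest.approx(1.0 / np.sqrt(8))


def test_tissue_summary_counts_and_stats():
    from drcsi.analysis import FractionMaps

    mwf = np.zeros((4, 1, 1))
    mwf[:2] = 0.1
    mwf[2:] = 0.2
    fm = FractionMaps(
        mwf=mwf,
        f_icec=1 - mwf,
        f_csf=np.zeros_like(mwf),
        mask=np.ones((4, 1, 1), bool),
        flagged=np.zeros((4, 1, 1), bool),
    )
    masks = {"A": np.array([1, 1, 0, 0], bool).reshape(4, 1, 1),
             "B": np.array([0, 0, 1, 1], bool).reshape(4, 1, 1)}
    tbl = tissue_summary(fm, masks).set_index("tissue")
    assert tbl.loc["A", "mean_mwf"] == pytest.approx(0.1)
    assert tbl.loc["B", "median_mwf"] == pytest.approx(0.2)
    assert tbl.loc["A", "n_voxels"] == 2
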