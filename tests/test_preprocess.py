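"""Signal conditioning: powder average, polarity, normalization, subsets."""

import dataclasses

import numpy as np
import pytest

from drcsi.phantom import default_phantom, simulate_dataset
from drcsi.preprocess import (
    extract_1d_subset,
    l2_normalize,
    polarity_correct,
    powder_average,
)
from drcsi.protocol import make_protocol_preset
from drcsi.volumes import SignalVolume


class TestPowderAverage:
    def test_isotropic_noiseless_average_is_exact(self):
        spec = default_phantom(12, snr=None)
        raw = simulate_dataset(spec, make_protocol_preset("t2d"), noise=None)
        sv = powder_average(raw)
        vox_raw = raw.data[raw.mask][0]
        vox = sv.masked()[0]
        for p in range(sv.P):
            vols = raw.volumes.loc[raw.volumes["contrast"] == p, "volume"].to_numpy()
            assert vox[p] == pytest.approx(vox_raw[vols[0]], rel=1e-14)

    def test_two_direction_mean(self):
        spec = default_phantom(12, snr=None)
        raw = simulate_dataset(spec, make_protocol_preset("t2d"), noise=None)
        # overwrite one two-direction contrast with known values
        p = 1
        vols = raw.volumes.loc[raw.volumes["contrast"] == p, "volume"].to_numpy()[:2]
        raw.data[..., vols[0]] = np.exp(-0.2)
        raw.data[..., vols[1]] = np.exp(-0.8)
        others = raw.volumes.loc[raw.volumes["contrast"] == p, "volume"].to_numpy()[2:]
        for v in others:
            raw.data[..., v] = (np.exp(-0.2) + np.exp(-0.8)) / 2
        sv = powder_average(raw)
        exact = (np.exp(-0.2) + np.exp(-0.8)) / 2
        assert sv.masked()[0, p] == pytest.approx(exact, rel=1e-12)
        assert sv.masked()[0, p] == pytest.approx(0.6340, abs=1e-4)

    def test_missing_direction_raises(self):
        spec = default_phantom(12, snr=None)
        raw = simulate_dataset(spec, make_protocol_preset("t1d"), noise=None)
        raw.volumes = raw.volumes.iloc[:-1]
        with pytest.raises(ValueError, match="direction"):
            powder_average(raw)


class TestPolarity:
    def _volume(self, data, prot, **flags):
        mask = np.ones(data.shape[:3], bool)
        return SignalVolume(data=data, mask=mask, protocol=prot, **flags)

    def test_single_compartment_zero_crossing(self):
        """T1 = 1000 ms, TR = 20 s: null at TI = T1 ln 2 ~ 693 ms, so TIs up
        to 412 ms flip negative and 697 ms upward stay positive."""
        prot = make_protocol_preset("t1t2")
        from drcsi.kernel import ir_factor

        signed = ir_factor(prot.TI, prot.TR, 1000.0) * np.exp(-prot.TE / 70.0)
        data = np.tile(np.abs(signed), (3, 3, 1, 1))
        sv = self._volume(data, prot, powder_averaged=True)
        out = polarity_correct(sv)
        rec = out.masked()[0]
        assert np.all(rec[prot.TI <= 412.0] < 0)
        assert np.all(rec[prot.TI >= 697.0] > 0)
        np.testing.assert_allclose(rec, signed, atol=1e-12)

    def test_idempotent_on_signed_input(self):
        prot = make_protocol_preset("t1t2")
        rng = np.random.default_rng(0)
        data = rng.random((2, 2, 1, prot.P))
        sv = self._volume(data, prot, polarity_corrected=True)
        out = polarity_correct(sv)
        np.testing.assert_array_equal(out.data, sv.data)

    def test_zero_voxel_untouched(self):
        prot = make_protocol_preset("t1t2")
        data = np.zeros((1, 1, 1, prot.P))
        out = polarity_correct(self._volume(data, prot))
        assert np.all(out.data == 0)

    def test_non_ir_protocol_warns_and_noop(self):
        prot = make_protocol_preset("t2d")
        data = np.abs(np.random.default_rng(1).random((2, 2, 1, prot.P)))
        sv = self._volume(data, prot)
        with pytest.warns(UserWarning, match="no inversion"):
            out = polarity_correct(sv)
        np.testing.assert_array_equal(out.data, sv.data)
        assert out.polarity_corrected

    def test_recovers_signs_on_noiseless_phantom(self):
        """Sign recovery on noiseless magnitude phantom data is >= 99%."""
        spec = default_phantom(16, snr=None)
        prot = make_protocol_preset("t1t2")
        raw_signed = simulate_dataset(spec, prot, noise=None)
        sv_signed = powder_average(raw_signed)
        sv_mag = dataclasses.replace(
            sv_signed.copy(), data=np.abs(sv_signed.data), polarity_corrected=False
        )
        out = polarity_correct(sv_mag)
        truth = sv_signed.masked()
        rec = out.masked()
        agree = np.mean(np.sign(rec) == np.sign(truth))
        assert agree >= 0.99


class TestNormalize:
    def test_three_four_five(self):
        prot = make_protocol_preset("t1t2")
        data = np.zeros((1, 1, 1, prot.P))
        data[0, 0, 0, 0] = 3.0
        data[0, 0, 0, 1] = 4.0
        sv = SignalVolume(
            data=data, mask=np.ones((1, 1, 1), bool), protocol=prot,
            polarity_corrected=True, powder_averaged=True,
        )
        out = l2_normalize(sv)
        assert out.data[0, 0, 0, 0] == pytest.approx(0.6)
        assert out.data[0, 0, 0, 1] == pytest.approx(0.8)
        assert np.linalg.norm(out.masked()[0]) == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self):
        prot = make_protocol_preset("t1t2")
        rng = np.random.default_rng(5)
        base = rng.random((2, 2, 1, prot.P))
        mask = np.ones((2, 2, 1), bool)
        a = l2_normalize(SignalVolume(base, mask, prot))
        b = l2_normalize(SignalVolume(base * 17.3, mask, prot))
        np.testing.assert_allclose(a.data, b.data, atol=1e-12)

    def test_tiny_norm_voxels_dropped_from_mask(self):
        prot = make_protocol_preset("t1t2")
        data = np.zeros((2, 1, 1, prot.P))
        data[0, 0, 0] = 1.0
        data[1, 0, 0] = 1e-12
        sv = SignalVolume(data, np.ones((2, 1, 1), bool), prot)
        out = l2_normalize(sv)
        assert out.mask[0, 0, 0] and not out.mask[1, 0, 0]


class TestExtract1D:
    @pytest.fixture(scope="class")
    def normalized(self):
        spec = default_phantom(12, snr=None)
        prot = make_protocol_preset("t1t2")
        raw = simulate_dataset(spec, prot, noise=None)
        sv = powder_average(raw)
        sv = dataclasses.replace(sv, polarity_corrected=True)
        return l2_normalize(sv)

    def test_t1_subset_is_eight_tis_at_min_te(self, normalized):
        sub = extract_1d_subset(normalized, "T1")
        assert sub.P == 8
        assert np.all(sub.protocol.TE == 4.5)
        np.testing.assert_array_equal(
            sub.protocol.TI, [50, 85, 143, 243, 412, 697, 1181, 2000]
        )

    def test_t2d_d_subset_at_min_te(self):
        spec = default_phantom(12, snr=None)
        prot = make_protocol_preset("t2d")
        raw = simulate_dataset(spec, prot, noise=None)
        sv = l2_normalize(powder_average(raw))
        sub = extract_1d_subset(sv, "D")
        assert sub.P == 8
        assert np.all(sub.protocol.TE == 21.0)
        np.testing.assert_array_equal(
            sub.protocol.b, [0, 50, 100, 200, 350, 550, 750, 1000]
        )

    def test_subset_of_subset_raises(self, normalized):
        sub = extract_1d_subset(normalized, "T1")
        with pytest.raises(ValueError):
            extract_1d_subset(sub, "T1")

    def test_unvaried_axis_raises(self, normalized):
        with pytest.raises(ValueError, match="not varied"):
            extract_1d_subset(normalized, "D")

    def test_fixed_negative_ir_weighting_flipped_positive(self, normalized):
        """The T2 subset at TI = 50 ms has net-negative signals (long-T1
        water dominates below its null); the per-voxel sign convention makes
        them representable by non-negative amplitudes."""
        sub = extract_1d_subset(normalized, "T2")
        sums = sub.masked().sum(axis=1)
        assert np.all(sums >= 0)
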