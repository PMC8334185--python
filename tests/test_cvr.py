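"""Analytic-signal coupling: band-limiting, delays, thresholding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvrpipe.cvr import (CvrMap, analytic, bandlimit, couple,
                         lagged_xcorr, map_cvr, threshold_map)
from cvrpipe.exceptions import DataError, DegenerateInputError
from cvrpipe.synthetic import region_regressor

FS = 0.8  # 1 / TR
F0 = 0.01
BAND = (0.004, 0.02)


@pytest.fixture(scope="module")
def reference(paradigm, volume_times):
    return region_regressor(paradigm, volume_times, 0.0)


def shifted(paradigm, volume_times, d):
    return region_regressor(paradigm, volume_times, d)


class TestBandlimit:
    def test_in_band_sinusoid_preserved(self):
        t = np.arange(2000) / FS
        x = np.sin(2 * np.pi * 0.009 * t)
        y = bandlimit(x, BAND, FS)
        mid = slice(400, 1600)
        amp = np.dot(y[mid], x[mid]) / np.dot(x[mid], x[mid])
        assert amp == pytest.approx(1.0, abs=0.02)

    def test_out_of_band_sinusoid_suppressed(self):
        t = np.arange(2000) / FS
        x = np.sin(2 * np.pi * 0.2 * t)  # 10x the upper edge
        y = bandlimit(x, BAND, FS)
        mid = slice(400, 1600)  # edge transients excluded
        amp = abs(np.dot(y[mid], x[mid]) / np.dot(x[mid], x[mid]))
        assert amp < 0.1

    def test_zero_in_zero_out(self):
        assert np.allclose(bandlimit(np.zeros(128), BAND, FS), 0.0)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandlimit(np.zeros(128), (0.01, 0.5), FS)


class TestAnalytic:
    def test_cosine_envelope_and_frequency(self):
        t = np.arange(4096) / FS
        f = 0.05
        a = analytic(np.cos(2 * np.pi * f * t))
        interior = slice(410, 3686)  # exclude 10% edges
        assert np.abs(np.abs(a[interior]) - 1.0).max() < 0.02
        inst_f = np.diff(np.unwrap(np.angle(a[interior]))) * FS / (2 * np.pi)
        assert np.median(inst_f) == pytest.approx(f, rel=0.01)

    def test_sine_lags_cosine_by_half_pi(self):
        t = np.arange(2048) / FS
        f = 0.05
        ac = analytic(np.cos(2 * np.pi * f * t))
        as_ = analytic(np.sin(2 * np.pi * f * t))
        interior = slice(205, 1843)
        dphi = np.angle(ac[interior] * np.conj(as_[interior]))
        assert np.median(dphi) == pytest.approx(np.pi / 2, abs=0.02)

    def test_chirp_instantaneous_frequency_tracks_sweep(self):
        from scipy.signal import chirp
        t = np.arange(4096) / FS
        x = chirp(t, f0=0.02, t1=t[-1], f1=0.08)
        a = analytic(x)
        mid = slice(1500, 2600)
        inst_f = np.diff(np.unwrap(np.angle(a))) * FS / (2 * np.pi)
        expect = 0.02 + (0.08 - 0.02) * t / t[-1]
        rel = np.abs(inst_f[mid] - expect[mid]) / expect[mid]
        assert np.median(rel) < 0.05

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            analytic(np.zeros(8))


class TestCouple:
    def test_self_coupling_is_one_at_zero_delay(self, reference):
        r, d = couple(reference, reference, fs=FS, f0=F0)
        assert r == pytest.approx(1.0, abs=1e-6)
        assert d == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("d", [-10.0, -5.0, 0.0, 3.0, 6.0, 10.0])
    def test_noise_free_shift_recovered(self, paradigm, volume_times,
                                        reference, d):
        vox = shifted(paradigm, volume_times, d)
        r, est = couple(vox, reference, fs=FS, f0=F0)
        assert r > 0.95
        assert est == pytest.approx(d, abs=0.625)

    def test_antisymmetry(self, paradigm, volume_times, reference):
        vox = shifted(paradigm, volume_times, 6.0)
        _, fwd = couple(vox, reference, fs=FS, f0=F0)
        _, rev = couple(reference, vox, fs=FS, f0=F0)
        assert fwd == pytest.approx(6.0, abs=0.625)
        assert rev == pytest.approx(-6.0, abs=0.625)

    def test_independent_noise_has_small_r(self, reference, rng):
        n_low = 0
        for _ in range(40):
            vox = rng.standard_normal(reference.size)
            r, _ = couple(vox, reference, fs=FS, f0=F0)
            n_low += abs(r) < 0.45
        assert n_low >= 36  # |r| stays small for ~95% of null draws

    def test_zero_variance_rejected(self, reference):
        with pytest.raises(DegenerateInputError):
            couple(np.zeros_like(reference), reference, fs=FS, f0=F0)

    def test_phase_method_agrees_with_oracle_for_sinusoid(self, rng):
        """For narrowband sinusoidal coupling at SNR >= 1 the analytic
        phase delay and the lagged-xcorr oracle agree within one TR."""
        t = np.arange(468) / FS
        x = np.sin(2 * np.pi * F0 * t)
        for i in range(100):
            d = rng.uniform(-10, 10)
            vox = np.sin(2 * np.pi * F0 * (t - d)) \
                + rng.standard_normal(t.size) * np.sqrt(0.5) / np.sqrt(2)
            _, dp = couple(vox, x, fs=FS, f0=F0, delay_method="phase")
            _, dx = lagged_xcorr(bandlimit(vox, BAND, FS),
                                 bandlimit(x, BAND, FS), 1.25, 20.0)
            assert abs(dp - dx) <= 1.25


class TestCoupleInvariances:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 50.0), offset=st.floats(-30.0, 30.0))
    def test_r_invariant_to_positive_rescale_and_offset(self, scale, offset):
        t = np.arange(468) / FS
        rng = np.random.default_rng(7)
        ref = np.sin(2 * np.pi * F0 * t) + 0.2 * np.sin(2 * np.pi * 2 * F0 * t)
        vox = ref + 0.3 * rng.standard_normal(t.size)
        r0, d0 = couple(vox, ref, fs=FS, f0=F0)
        r1, d1 = couple(scale * vox + offset, ref, fs=FS, f0=F0)
        assert r1 == pytest.approx(r0, abs=1e-9)
        assert d1 == pytest.approx(d0, abs=1e-9)


class TestMapCvr:
    def test_region_delays_recovered(self, paradigm, volume_times,
                                     reference, rng):
        delays = {1: 0.0, 2: 3.0, 3: 6.0}
        labels = np.zeros((6, 3, 1), dtype=int)
        labels[0:2] = 1
        labels[2:4] = 2
        labels[4:6] = 3
        data = np.zeros((6, 3, 1, reference.size))
        for lab, d in delays.items():
            sig = shifted(paradigm, volume_times, d)
            sel = labels == lab
            data[sel] = sig + 0.1 * np.std(sig) \
                * rng.standard_normal((sel.sum(), sig.size))
        mask = labels > 0
        cvr = map_cvr(data, reference, mask, fs=FS, f0=F0)
        for lab, d in delays.items():
            med = np.median(cvr.delay[labels == lab])
            assert med == pytest.approx(d, abs=0.625)

    def test_single_voxel_mask(self, reference):
        data = np.zeros((2, 2, 1, reference.size))
        data[0, 0, 0] = reference
        mask = np.zeros((2, 2, 1), dtype=bool)
        mask[0, 0, 0] = True
        cvr = map_cvr(data, reference, mask, fs=FS, f0=F0)
        assert cvr.r[0, 0, 0] == pytest.approx(1.0, abs=1e-6)
        assert np.isnan(cvr.r[1, 1, 0])

    def test_zero_variance_voxels_excluded(self, reference):
        data = np.zeros((2, 1, 1, reference.size))
        data[0, 0, 0] = reference
        mask = np.ones((2, 1, 1), dtype=bool)
        cvr = map_cvr(data, reference, mask, fs=FS, f0=F0)
        assert np.isnan(cvr.r[1, 0, 0])

    def test_grid_mismatch_rejected(self, reference):
        with pytest.raises(DataError):
            map_cvr(np.zeros((2, 2, 2, reference.size)), reference,
                    np.ones((3, 3, 3), dtype=bool), fs=FS, f0=F0)


class TestThresholdMap:
    def _map_with_p(self, p_values, shape=(4, 4, 2)):
        r = np.full(shape, 0.8)
        delay = np.zeros(shape)
        mask = np.ones(shape, dtype=bool)
        cvr = CvrMap(r, delay, mask)
        cvr.p = p_values
        return cvr

    def test_zero_extent_is_pure_voxel_threshold(self):
        p = np.full((4, 4, 2), 0.5)
        p[0, 0, 0] = 1e-4
        out = threshold_map(self._map_with_p(p), 0.005, 0.0,
                            (3.4375, 3.4375, 6.0))
        assert np.isfinite(out.r[0, 0, 0])
        assert np.isnan(out.r[1, 1, 1])

    def test_single_voxel_removed_by_226mm3_extent(self):
        # EPI voxel 3.4375 x 3.4375 x 6 mm = 70.9 mm^3: a 226 mm^3 extent
        # requires at least 4 contiguous voxels
        p = np.full((6, 6, 2), 0.5)
        p[0, 0, 0] = 1e-4
        out = threshold_map(self._map_with_p(p, (6, 6, 2)), 0.005, 226.0,
                            (3.4375, 3.4375, 6.0))
        assert np.all(np.isnan(out.r))

    def test_blob_of_ten_voxels_retained_intact(self):
        p = np.full((6, 6, 2), 0.5)
        p[1:6, 2, 0] = 1e-4
        p[1:6, 3, 0] = 1e-4
        out = threshold_map(self._map_with_p(p, (6, 6, 2)), 0.005, 226.0,
                            (3.4375, 3.4375, 6.0))
        assert np.isfinite(out.r[1:6, 2:4, 0]).all()
        assert np.isnan(out.r[0, 0, 0])

    def test_negative_extent_rejected(self):
        with pytest.raises(ValueError):
            threshold_map(self._map_with_p(np.full((4, 4, 2), 0.5)),
                          0.005, -1.0, (3.4, 3.4, 6.0))

    def test_missing_p_rejected(self):
        cvr = CvrMap(np.zeros((2, 2, 2)), np.zeros((2, 2, 2)),
                     np.ones((2, 2, 2), dtype=bool))
        with pytest.raises(DataError):
            threshold_map(cvr, 0.005, 0.0, (3.4, 3.4, 6.0))
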