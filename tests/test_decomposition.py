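"""Elevation angle, per-frequency resampling and the wavelet levels."""

import numpy as np
import pytest
import pywt
from numpy.fft import rfft, rfftfreq

from tremorindex.decomposition import (
    ElevationSeries,
    elevation,
    level_for_frequency,
    min_length,
    mra,
    resample,
    target_rate,
    target_ratio,
)
from tremorindex.errors import DomainError, LengthError


def band_energy(x, fs, lo, hi):
    spec = np.abs(rfft(x)) ** 2
    freqs = rfftfreq(len(x), 1 / fs)
    total = spec[1:].sum()
    return spec[(freqs > lo) & (freqs <= hi)].sum() / total if total else 0.0


class TestElevation:
    def test_zero_and_unit_gravity(self, make_recording):
        rec = make_recording(1.0, az=0.0)
        np.testing.assert_array_equal(elevation(rec).theta, 0.0)
        rec = make_recording(1.0, az=1.0)
        np.testing.assert_allclose(elevation(rec).theta, np.pi / 4)

    def test_odd_symmetry(self, make_recording):
        up = elevation(make_recording(1.0, az=1.0)).theta
        down = elevation(make_recording(1.0, az=-1.0)).theta
        np.testing.assert_allclose(down, -up)

    def test_range_is_open_interval(self, make_recording):
        rec = make_recording(1.0, az=1e6)
        theta = elevation(rec).theta
        assert np.all(np.abs(theta) < np.pi / 2)


class TestTargetRate:
    @pytest.mark.parametrize("f,expected", [(3, 8.0), (6, 16.0), (12, 32.0)])
    def test_band_centre_rates(self, f, expected):
        assert target_rate(f) == pytest.approx(expected)

    @pytest.mark.parametrize("f", range(3, 13))
    def test_first_band_centred_on_f(self, f):
        fs_f = target_rate(f)
        lo, hi = fs_f / 4, fs_f / 2
        assert lo < f <= hi
        assert 3 * fs_f / 8 == pytest.approx(f)
        assert fs_f <= 32.0

    @pytest.mark.parametrize("f", [2, 13, 5.5])
    def test_out_of_range_rejected(self, f):
        with pytest.raises(DomainError):
            target_rate(f)

    def test_ratio_is_small_rational(self):
        from fractions import Fraction

        assert target_ratio(9) == Fraction(3, 4)
        assert target_ratio(5) == Fraction(5, 12)


class TestResample:
    def test_dc_preserved(self):
        es = ElevationSeries(np.full(3200, 0.7), 32.0, 0.0)
        out = resample(es, 8.0)
        assert out.fs == 8.0
        np.testing.assert_allclose(out.theta[10:-10], 0.7, rtol=1e-6)

    def test_in_band_sinusoid_amplitude_kept(self):
        t = np.arange(3200) / 32.0
        es = ElevationSeries(np.sin(2 * np.pi * 2.0 * t), 32.0, 0.0)
        out = resample(es, 8.0)
        # FFT amplitude oracle: 2 Hz is below the 4 Hz output Nyquist
        assert band_energy(out.theta, 8.0, 1.5, 2.5) > 0.99

    def test_above_nyquist_content_removed(self):
        t = np.arange(3200) / 32.0
        es = ElevationSeries(np.sin(2 * np.pi * 10.0 * t), 32.0, 0.0)
        out = resample(es, 8.0)
        assert np.max(np.abs(out.theta[20:-20])) < 0.05

    def test_duration_within_one_sample(self):
        es = ElevationSeries(np.zeros(3217), 32.0, 0.0)
        out = resample(es, 8.0)
        assert abs(len(out.theta) / 8.0 - 3217 / 32.0) <= 1 / 8.0

    def test_gapwise_resampling_never_crosses_gap(self):
        theta = np.concatenate([np.full(3200, 1.0), np.full(3200, -1.0)])
        es = ElevationSeries(theta, 32.0, 0.0, gaps=[(100.0, 200.0)])
        out = resample(es, 8.0)
        chunks = out.chunks()
        assert len(chunks) == 2
        # each chunk keeps its own DC value; no blending across the gap
        t0, a, b = chunks[0]
        np.testing.assert_allclose(out.theta[a + 15 : b - 15], 1.0, rtol=1e-6)
        t1, a, b = chunks[1]
        assert t1 == 200.0
        np.testing.assert_allclose(out.theta[a + 15 : b - 15], -1.0, rtol=1e-6)

    def test_upsampling_rejected(self):
        with pytest.raises(DomainError):
            resample(ElevationSeries(np.zeros(64), 8.0, 0.0), 32.0)


class TestMRA:
    def test_additive_reconstruction(self, rng):
        x = rng.standard_normal(4096)
        details, smooth = mra(x)
        np.testing.assert_allclose(
            np.sum(details, axis=0) + smooth, x,
            rtol=0, atol=1e-8 * np.max(np.abs(x)),
        )

    def test_zero_input_gives_zero_components(self):
        details, smooth = mra(np.zeros(512))
        assert all(np.allclose(d, 0) for d in details)
        assert np.allclose(smooth, 0)

    def test_too_short_reports_minimum(self):
        with pytest.raises(LengthError) as exc:
            mra(np.zeros(16))
        assert exc.value.min_length == min_length()

    def test_white_noise_detail1_band(self, rng):
        # detail 1 of a 32 Hz decomposition should live in (8, 16] Hz
        x = rng.standard_normal(2**14)
        details, _ = mra(x, depth=2)
        assert band_energy(details[0], 32.0, 8.0, 16.0) >= 0.85

    def test_matches_pywt_mra(self, rng):
        """Independent cross-check against the reference SWT-MRA."""
        x = rng.standard_normal(2048)
        details, smooth = mra(x, "db4", 3)
        ref = pywt.mra(x, "db4", level=3, transform="swt")
        # interiors must agree exactly; boundary treatment differs
        # (reflection here vs periodization there)
        sl = slice(300, -300)
        np.testing.assert_allclose(smooth[sl], ref[0][sl], atol=1e-10)
        for j in range(3):
            np.testing.assert_allclose(details[j][sl], ref[-(j + 1)][sl],
                                       atol=1e-10)

    def test_coefficient_energy_conserved(self, rng):
        """Orthonormal analysis preserves total energy within 1%."""
        from tremorindex._modwt import analysis

        x = rng.standard_normal(2**13)
        details, approx = analysis(x, "db4", 4)
        coeff_energy = sum(float(d @ d) for d in details) + float(approx @ approx)
        assert coeff_energy == pytest.approx(float(x @ x), rel=0.01)


class TestLevelForFrequency:
    def test_pure_tone_energy_concentrates_at_its_level(self, sine_elevation):
        es = sine_elevation(5.0, 0.1, duration_s=1800.0)
        energies = {}
        for f in (3, 5, 9):
            lv = level_for_frequency(es, f)
            energies[f] = float(np.mean(lv.values[lv.valid] ** 2))
        assert energies[5] >= 5 * energies[3]
        assert energies[5] >= 5 * energies[9]

    def test_constant_input_lives_in_smooth(self):
        es = ElevationSeries(np.full(6400, 0.3), 32.0, 0.0)
        lv = level_for_frequency(es, 6, include_smooth=True)
        assert np.max(np.abs(lv.values[lv.valid])) < 1e-9
        # the smooth's support is ~2**J times wider than the detail's, so
        # judge it on the interior, clear of the resampler's edge ripple
        sm = lv.smooth[lv.valid][150:-150]
        np.testing.assert_allclose(sm, 0.3, rtol=1e-6)

    def test_slow_activity_rejected_at_all_levels(self):
        t = np.arange(32 * 1200) / 32.0
        es = ElevationSeries(0.5 * np.sin(2 * np.pi * 0.5 * t), 32.0, 0.0)
        in_energy = float(np.mean(es.theta**2))
        for f in range(3, 13):
            lv = level_for_frequency(es, f)
            assert np.mean(lv.values[lv.valid] ** 2) < 0.02 * in_energy

    @pytest.mark.parametrize("f", [3, 7, 11])
    def test_frequency_assignment_within_one(self, sine_elevation, f):
        es = sine_elevation(float(f), 0.05, duration_s=900.0, start_epoch=0.0)
        energies = {
            fp: float(np.mean(level_for_frequency(es, fp).values ** 2))
            for fp in range(3, 13)
        }
        best = max(energies, key=energies.get)
        assert abs(best - f) <= 1

    def test_band_metadata(self, sine_elevation):
        lv = level_for_frequency(sine_elevation(5.0, 0.01, 300.0), 5)
        assert lv.fs_f == pytest.approx(40 / 3)
        assert lv.band == pytest.approx((10 / 3, 20 / 3))
        assert lv.f == 5

    def test_short_chunks_become_gaps(self):
        theta = np.zeros(32 * 100)
        es = ElevationSeries(theta, 32.0, 0.0, gaps=[(98.0, 99.0)])
        # second chunk after the gap is 1 s = far below the MRA minimum
        lv = level_for_frequency(es, 3)
        assert len(lv.chunks()) == 1
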