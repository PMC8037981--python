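"""EMD and Hilbert-phase contracts: extrema, envelopes, sifting,
completeness, oracle equivalence, phase calibration."""

import numpy as np
import pytest

from bcgbp import (
    CannotSiftError,

    emd_decompose,
    envelope_mean,
    find_extrema,
    hilbert_phase,
    instantaneous_frequency,
    sift,
)
from conftest import band_limited_noise, two_tone
from reference_emd import reference_imf1

INTERIOR = slice(100, 900)  # central 80% of a 1000-sample signal


def mean_frequency(x, fs):
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), 1 / fs)
    return np.sum(freqs * spec) / np.sum(spec)


class TestFindExtrema:
    def test_single_peak(self):
        maxima, minima = find_extrema(np.array([0.0, 1.0, 0.0]))
        assert maxima.tolist() == [1] and minima.size == 0

    def test_monotone_ramp_has_no_extrema(self):
        maxima, minima = find_extrema(np.linspace(0, 1, 50))
        assert maxima.size == 0 and minima.size == 0

    def test_sine_extrema_at_analytic_times(self):
        fs = 100.0
        t = np.arange(100) / fs
        maxima, minima = find_extrema(np.sin(2 * np.pi * 2.0 * t))
        # 2 Hz over 1 s: maxima at 0.125 s and 0.625 s, minima at 0.375, 0.875
        assert len(maxima) == 2 and len(minima) == 2
        assert np.allclose(maxima, [12.5, 62.5], atol=1.0)
        assert np.allclose(minima, [37.5, 87.5], atol=1.0)

    def test_plateau_contributes_midpoint(self):
        x = np.array([0.0, 1.0, 2.0, 2.0, 2.0, 1.0, 0.0])
        maxima, _ = find_extrema(x)
        assert maxima.tolist() == [3]

    def test_maxima_minima_interleave(self):
        rng = np.random.default_rng(0)
        x = band_limited_noise(rng)
        maxima, minima = find_extrema(x)
        merged = sorted([(i, "M") for i in maxima] + [(i, "m") for i in minima])
        kinds = [k for _, k in merged]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            find_extrema(np.array([0.0, 1.0]))


class TestEnvelopeMean:
    def test_pure_sinusoid_mean_near_zero(self):
        t = np.arange(1000) / 100.0
        m = envelope_mean(np.sin(2 * np.pi * 3.0 * t))
        assert np.max(np.abs(m[INTERIOR])) < 0.05

    def test_shift_equivariance(self):
        t = np.arange(1000) / 100.0
        x = np.sin(2 * np.pi * 3.0 * t)
        m0 = envelope_mean(x)
        m7 = envelope_mean(x + 7.0)
        assert np.allclose(m7[INTERIOR], m0[INTERIOR] + 7.0, atol=1e-9)
        assert np.max(np.abs(m7[INTERIOR] - 7.0)) < 0.05

    def test_envelopes_bracket_signal_at_knots(self):
        from bcgbp import spline_envelopes

        rng = np.random.default_rng(2)
        x = band_limited_noise(rng)
        upper, lower = spline_envelopes(x)
        maxima, minima = find_extrema(x)
        # each envelope interpolates its own extrema exactly ...
        assert np.allclose(upper[maxima], x[maxima], atol=1e-9)
        assert np.allclose(lower[minima], x[minima], atol=1e-9)
        # ... and brackets the opposite extrema up to the small cubic-spline
        # overshoot that envelope interpolation is known to exhibit
        tol = 0.05 * np.ptp(x)
        assert np.all(upper[minima] >= x[minima] - tol)
        assert np.all(lower[maxima] <= x[maxima] + tol)
        m = envelope_mean(x)
        assert np.allclose(m, (upper + lower) / 2.0)

    def test_two_tone_mean_tracks_slow_component(self):
        t, slow, fast, x = two_tone()
        m = envelope_mean(x)
        r = np.corrcoef(m[INTERIOR], slow[INTERIOR])[0, 1]
        assert r > 0.95

    def test_too_few_extrema_signals_cannot_sift(self):
        with pytest.raises(CannotSiftError):
            envelope_mean(np.linspace(0.0, 1.0, 100))


class TestSift:
    def test_clean_sinusoid_is_fixed_point(self):
        t = np.arange(1000) / 100.0
        x = np.sin(2 * np.pi * 3.0 * t)
        h = sift(x)
        rms = np.sqrt(np.mean((h[INTERIOR] - x[INTERIOR]) ** 2))
        assert rms < 0.01 * np.sqrt(0.5)

    def test_two_tone_yields_fast_component(self):
        t, slow, fast, x = two_tone()
        h = sift(x)
        r = np.corrcoef(h[INTERIOR], fast[INTERIOR])[0, 1]
        assert r > 0.95

    def test_imf_zero_crossings_match_extrema_within_one(self):
        t, _, _, x = two_tone()
        h = sift(x)
        maxima, minima = find_extrema(h)
        crossings = np.sum(np.abs(np.diff(np.sign(h))) > 1)
        assert abs(crossings - (len(maxima) + len(minima))) <= 1


class TestEmdDecompose:
    def test_monotone_input_yields_zero_imfs(self):
        x = np.linspace(0.0, 1.0, 100)
        out = emd_decompose(x)
        assert out.n == 0
        assert np.array_equal(out.residue, x)

    def test_completeness_on_random_band_limited_signals(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            x = band_limited_noise(rng)
            out = emd_decompose(x)
            err = np.max(np.abs(out.reconstruct() - x)) / np.max(np.abs(x))
            assert err < 1e-8

    def test_imf_frequencies_descend_for_two_tone(self):
        t, _, _, x = two_tone()
        out = emd_decompose(x)
        assert out.n >= 2
        f1 = mean_frequency(out.imfs[0], 100.0)
        f2 = mean_frequency(out.imfs[1], 100.0)
        assert f1 > f2

    def test_decomposition_terminates_on_exhausted_residue(self):
        # the final residue cannot support another envelope pair: either
        # fewer than 2 extrema in total (monotone-like) or fewer than 2
        # maxima / 2 minima (no spline knots left)
        rng = np.random.default_rng(3)
        x = band_limited_noise(rng) + np.linspace(0, 4, 1000)
        out = emd_decompose(x)
        maxima, minima = find_extrema(out.residue)
        assert len(maxima) + len(minima) < 2 or len(maxima) < 2 or len(minima) < 2

    def test_oracle_equivalence_on_two_tones(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            _, _, fast, x = two_tone(
                phase_slow=rng.uniform(0, 2 * np.pi),
                phase_fast=rng.uniform(0, 2 * np.pi),
                amp_slow=rng.uniform(0.5, 1.5),
            )
            ours = emd_decompose(x).imfs[0]
            ref = reference_imf1(x)
            r = np.corrcoef(ours[INTERIOR], ref[INTERIOR])[0, 1]
            assert r > 0.99

    def test_bcg_imf1_frequency_in_analysis_band(self, rest_pipeline):
        from bcgbp import FilterSpec, bandpass_filter, default_config, simulate_session

        cfg = default_config("rest", noise_sd=0.0, seed=13)
        rec, _ = simulate_session(cfg)
        filt = bandpass_filter(rec, FilterSpec(fs=rec.fs))
        imf1 = emd_decompose(filt.ch_back).imfs[0]
        assert 0.5 <= mean_frequency(imf1, rec.fs) <= 6.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            emd_decompose(np.arange(5.0))


class TestHilbertPhase:
    def test_cosine_phase_slope(self):
        fs = 100.0
        t = np.arange(500) / fs
        ps = hilbert_phase(np.cos(2 * np.pi * 2.0 * t), fs)
        unwrapped = ps.unwrapped()
        i = slice(50, 450)
        slope = np.polyfit(t[i], unwrapped[i], 1)[0]
        assert slope == pytest.approx(4 * np.pi, rel=0.01)

    def test_quadrature_offset(self):
        fs = 100.0
        t = np.arange(500) / fs
        w = 2 * np.pi * 2.0
        p_sin = hilbert_phase(np.sin(w * t), fs).unwrapped()
        p_cos = hilbert_phase(np.cos(w * t), fs).unwrapped()
        diff = p_sin[50:450] - p_cos[50:450]
        assert np.allclose(diff, -np.pi / 2, atol=0.05)

    def test_chirp_instantaneous_frequency(self):
        from scipy.signal import chirp

        fs = 100.0
        t = np.arange(2000) / fs
        x = chirp(t, f0=1.0, f1=5.0, t1=t[-1], method="linear")
        ps = hilbert_phase(x, fs)
        freq = instantaneous_frequency(ps)
        expected = 1.0 + (5.0 - 1.0) * t[:-1] / t[-1]
        i = slice(200, 1800)
        assert np.max(np.abs(freq[i] - expected[i]) / expected[i]) < 0.05

    def test_wrapped_range(self, rest_pipeline):
        *_, back, seat = rest_pipeline
        for ps in (back, seat):
            assert np.all(ps.phase > -np.pi)
            assert np.all(ps.phase <= np.pi)

    def test_unwrap_rewrap_roundtrip(self, rest_pipeline):
        *_, back, _ = rest_pipeline
        rewrapped = np.angle(np.exp(1j * back.unwrapped()))
        assert np.allclose(rewrapped, back.phase, atol=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            hilbert_phase(np.ones(100), 100.0)


class TestInstantaneousFrequency:
    def test_median_frequency_of_cosine(self):
        fs = 100.0
        t = np.arange(500) / fs
        ps = hilbert_phase(np.cos(2 * np.pi * 2.0 * t), fs)
        freq = instantaneous_frequency(ps)
        assert np.median(freq) == pytest.approx(2.0, rel=0.01)
        assert freq.shape[0] == len(ps) - 1

    def test_constant_phase_gives_zero(self):
        from bcgbp import PhaseSeries

        ps = PhaseSeries(phase=np.full(50, 0.3), fs=100.0)
        assert np.allclose(instantaneous_frequency(ps), 0.0)
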