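import numpy as np
import pytest

from hsfibi.harsum import (AmplitudeSpectrum, KernelSpec, estimate_window_hr,
                           f0_grid, fft_spectrum, harsum_spectrum,
                           kernel_value, preprocess_harsum, sliding_hr)
from hsfibi.io import ChannelSignal

from conftest import make_pulse_train


def harsum_oracle(X, grid, multipliers):
    """Direct double-loop evaluation of the harmonic-summation inner product."""
    out = np.zeros(len(grid))
    for g, f in enumerate(grid):
        total = 0.0
        for i in multipliers:
            if (i + 0.5) * f > X.freqs_hz[-1]:
                continue
            peak = np.interp(i * f, X.freqs_hz, X.amps)
            v_lo = np.interp((i - 0.5) * f, X.freqs_hz, X.amps)
            v_hi = np.interp((i + 0.5) * f, X.freqs_hz, X.amps)
            total += peak / i - (v_lo + v_hi) / (2.0 * i)
        out[g] = total
    return out


class TestKernel:
    def test_peak_at_fundamental(self):
        assert kernel_value(1.3, 1.3) == pytest.approx(1.0, abs=1e-12)

    def test_valley_at_three_halves(self):
        # i=1 contributes -1/2 at (1+1/2) f0, i=2 contributes -1/4 at (2-1/2) f0
        assert kernel_value(1.5 * 1.2, 1.2) == pytest.approx(-0.75, abs=1e-12)

    def test_fourth_harmonic_unweighted(self):
        # 4 is neither in {1,2,3,5,7} nor a half-integer multiple offset
        assert kernel_value(4 * 0.9, 0.9) == pytest.approx(0.0, abs=1e-12)

    def test_zero_mass_per_multiplier(self):
        # each i places +1/i and two -1/(2i): net mass zero
        for i in (1, 2, 3, 5, 7):
            spec = KernelSpec(multipliers=(i,))
            total = sum(kernel_value(r * 1.0, 1.0, spec)
                        for r in (i, i - 0.5, i + 0.5))
            assert total == pytest.approx(0.0, abs=1e-12)


class TestHarsumSpectrum:
    def _impulse_train(self, f0=1.0, mass=0.3, top=25.0, df=0.0125):
        freqs = np.arange(0.0, top + df / 2, df)
        amps = np.zeros_like(freqs)
        for k in range(1, 8):
            amps[int(round(k * f0 / df))] = mass
        return AmplitudeSpectrum(freqs, amps)

    def test_impulse_train_closed_form(self):
        X = self._impulse_train(mass=0.3)
        hs = harsum_spectrum(X, np.array([1.0]))
        expected = 0.3 * sum(1.0 / i for i in (1, 2, 3, 5, 7))
        assert hs[0] == pytest.approx(expected, abs=1e-9)

    def test_octave_scores_below_fundamental(self):
        X = self._impulse_train()
        hs = harsum_spectrum(X, np.array([1.0, 2.0]))
        assert hs[1] < hs[0]

    def test_flat_spectrum_is_zero(self):
        freqs = np.arange(0.0, 30.0, 0.01)
        X = AmplitudeSpectrum(freqs, np.full_like(freqs, 0.37))
        hs = harsum_spectrum(X, np.arange(0.7, 3.0, 0.1))
        assert np.max(np.abs(hs)) < 1e-9

    def test_matches_double_loop_oracle_on_random_spectra(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            freqs = np.linspace(0.0, rng.uniform(15, 30), rng.integers(200, 800))
            amps = rng.random(len(freqs))
            X = AmplitudeSpectrum(freqs, amps)
            grid = np.sort(rng.uniform(0.7, 3.0, 40))
            np.testing.assert_allclose(
                harsum_spectrum(X, grid),
                harsum_oracle(X, grid, (1, 2, 3, 5, 7)), atol=1e-9)

    def test_empty_grid_rejected(self):
        X = self._impulse_train()
        with pytest.raises(ValueError):
            harsum_spectrum(X, np.array([]))


class TestPreprocessAndSpectrum:
    def test_zscore_before_squaring(self, cfg):
        rng = np.random.default_rng(0)
        x = rng.normal(3.0, 2.5, 2000)
        z = (x - x.mean()) / x.std()
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, abs=1e-12)

    def test_constant_window_unusable(self, cfg):
        x = ChannelSignal(np.full(2000, 2.0), 250.0, "const")
        res = estimate_window_hr(x, cfg)
        assert not res.usable and res.sqi == 0.0

    def test_pulse_train_demodulates_to_rate_harmonics(self, cfg):
        # squaring + band-pass turns a 1.2 Hz pulse train into a comb at
        # multiples of 1.2 Hz.  The raw spectral peak may sit on a higher
        # harmonic (the 1 Hz cutoff attenuates a 1.2 Hz fundamental) — the
        # kernel stage exists to undo exactly that — but the harmonic-
        # summation estimate must land on the true rate.
        sr = 250.0
        sig = make_pulse_train(1 / 1.2, 8.0, sr)
        y = preprocess_harsum(ChannelSignal(sig, sr, "pt"), cfg)
        X = fft_spectrum(y, cfg)
        band = (X.freqs_hz > 0.7) & (X.freqs_hz < 10.0)
        peak_f = X.freqs_hz[band][np.argmax(X.amps[band])]
        assert min(abs(peak_f - k * 1.2) for k in (1, 2, 3)) < 0.05
        res = estimate_window_hr(ChannelSignal(sig, sr, "pt"), cfg)
        assert res.hr_bpm == pytest.approx(72.0, abs=2.0)

    def test_single_tone_peak_location(self, cfg):
        sr = 250.0
        t = np.arange(int(8 * sr)) / sr
        y = ChannelSignal(np.sin(2 * np.pi * 2.0 * t), sr, "tone")
        X = fft_spectrum(y, cfg)
        assert X.freqs_hz[np.argmax(X.amps)] == pytest.approx(2.0, abs=0.02)

    def test_two_tone_local_maxima(self, cfg):
        sr = 250.0
        t = np.arange(int(8 * sr)) / sr
        y = ChannelSignal(np.sin(2 * np.pi * 1.5 * t)
                          + np.sin(2 * np.pi * 3.0 * t), sr, "two")
        X = fft_spectrum(y, cfg)
        for f in (1.5, 3.0):
            near = np.abs(X.freqs_hz - f) < 0.1
            far_lo = np.abs(X.freqs_hz - f) < 0.3
            assert X.amps[near].max() == X.amps[far_lo].max()

    def test_tone_normalisation_rate_invariant(self, cfg):
        # the SQI scale (hence the Q1/Q2 thresholds) must not depend on the
        # sampling rate: a pure in-band tone reads the same fixed constant
        peaks = []
        for sr in (125.0, 250.0, 1000.0):
            t = np.arange(int(8 * sr)) / sr
            y = ChannelSignal(np.sin(2 * np.pi * 2.0 * t), sr, "tone")
            peaks.append(fft_spectrum(y, cfg).amps.max())
        assert max(peaks) - min(peaks) < 0.02 * peaks[0]
        assert 0.6 < peaks[0] < 0.85


class TestWindowEstimation:
    def test_known_rate_recovered(self, cfg):
        sr = 250.0
        sig = make_pulse_train(60 / 72.0, 8.0, sr)
        res = estimate_window_hr(ChannelSignal(sig, sr, "hr72"), cfg)
        assert res.hr_bpm == pytest.approx(72.0, abs=2.0)
        assert res.sqi == pytest.approx(np.max(res.hs))
        assert res.hr_bpm == pytest.approx(60.0 * res.f0_hz)

    def test_no_octave_error_with_dominant_second_harmonic(self, cfg):
        sr, hr = 250.0, 66.0
        f0 = hr / 60.0
        t = np.arange(int(8 * sr)) / sr
        sig = (0.05 * np.cos(2 * np.pi * f0 * t)      # fundamental / 20
               + 1.0 * np.cos(2 * np.pi * 2 * f0 * t)
               + 0.3 * np.cos(2 * np.pi * 3 * f0 * t))
        res = estimate_window_hr(ChannelSignal(sig, sr, "h2"), cfg)
        assert res.hr_bpm == pytest.approx(hr, abs=3.0)

    def test_scale_invariance(self, cfg):
        rng = np.random.default_rng(8)
        sig = make_pulse_train(0.8, 8.0, 250.0) + rng.normal(0, 0.1, 2000)
        base = estimate_window_hr(ChannelSignal(sig, 250.0, "s"), cfg)
        for c in (-2.0, 0.25, 40.0):
            res = estimate_window_hr(ChannelSignal(c * sig, 250.0, "s"), cfg)
            assert res.hr_bpm == base.hr_bpm
            assert res.sqi == pytest.approx(base.sqi, rel=1e-9)

    def test_harmonic_dominance_sweep(self, cfg):
        # any single harmonic (order <= 3) amplified up to 3x keeps the argmax
        # at the true fundamental within one grid bin
        sr = 250.0
        t = np.arange(int(8 * sr)) / sr
        for f0 in (1.1, 1.4):
            for order in (2, 3):
                for gain in (1.5, 3.0):
                    amps = {1: 1.0, 2: 0.6, 3: 0.4}
                    amps[order] *= gain
                    sig = sum(a * np.cos(2 * np.pi * k * f0 * t + 0.7 * k)
                              for k, a in amps.items())
                    res = estimate_window_hr(ChannelSignal(sig, sr, "sw"), cfg)
                    assert abs(res.f0_hz - f0) <= cfg.f0_grid_step_hz + 1e-9, (
                        f0, order, gain)

    def test_white_noise_sqi_below_q2(self, cfg):
        rng = np.random.default_rng(42)
        sqis = [estimate_window_hr(
            ChannelSignal(rng.normal(size=2000), 250.0, "n"), cfg).sqi
            for _ in range(100)]
        assert np.percentile(sqis, 95) < cfg.q2


class TestSlidingWindows:
    def test_window_count_10s(self, cfg):
        x = ChannelSignal(np.random.default_rng(0).normal(size=2500), 250.0, "w")
        assert len(sliding_hr(x, cfg)) == 3  # t = 0, 1, 2

    def test_window_count_exact_8s(self, cfg):
        x = ChannelSignal(np.random.default_rng(0).normal(size=2000), 250.0, "w")
        assert len(sliding_hr(x, cfg)) == 1

    def test_too_short_empty(self, cfg):
        x = ChannelSignal(np.zeros(100), 250.0, "w")
        assert sliding_hr(x, cfg) == []

    def test_constant_rate_stable_track(self, cfg):
        sig = make_pulse_train(60 / 70.0, 60.0, 250.0)
        results = sliding_hr(ChannelSignal(sig, 250.0, "t"), cfg)
        hrs = np.array([r.hr_bpm for r in results])
        assert np.std(hrs) < 1.0
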