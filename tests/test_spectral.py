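import numpy as np
import pytest

from burstcount import EpochArray, FREQ_GRID, apply_baseline, bandpass
from burstcount.containers import TFDecomposition
from burstcount.design import epoch_times
from burstcount.spectral import (
    band_edges,
    entrainment_windows,
    hilbert_tf,
    window_mean_amplitude,
)

T = epoch_times()


def sinusoid(freq, amp=1.0):
    return amp * np.sin(2 * np.pi * freq * T)

MID = slice(360, 1560)  # central 1 s, clear of filter edge effects


class TestBandpass:
    def test_in_band_identity(self):
        x = sinusoid(10, 2.0)
        y = bandpass(x, 10)
        np.testing.assert_allclose(y[MID], x[MID], atol=0.05 * 2.0)

    def test_out_of_band_attenuation(self):
        x = sinusoid(40)
        y = bandpass(x, 10)
        assert np.abs(y[MID]).max() < 0.05

    def test_low_centre_clips_highpass_edge(self):
        lo, hi = band_edges(3)
        assert lo == 0.5 and hi == 6.0
        y = bandpass(sinusoid(3), 3)  # filter must be constructible and stable
        assert np.isfinite(y).all()

    def test_empty_passband_raises(self):
        with pytest.raises(ValueError):
            band_edges(100, 6, fs=150)


class TestHilbertTF:
    @pytest.mark.parametrize("method", ["fft", "sos"])
    def test_sinusoid_envelope(self, method):
        ep = EpochArray(sinusoid(10, 2.5))
        tf = hilbert_tf(ep, np.array([10.0]), method=method)
        assert tf.amplitude[0, 0, MID] == pytest.approx(2.5, rel=0.05)

    def test_two_component_crosstalk(self):
        ep = EpochArray(sinusoid(10, 1.0) + sinusoid(40, 1.0))
        tf = hilbert_tf(ep, np.array([10.0, 40.0]))
        for i in range(2):
            assert np.median(tf.amplitude[0, i, MID]) == pytest.approx(1.0, rel=0.05)
        # amplitude attributable to the other component stays small
        ep10 = hilbert_tf(EpochArray(sinusoid(10)), np.array([40.0]))
        assert ep10.amplitude[0, 0, MID].max() < 0.05

    def test_zero_epoch(self):
        tf = hilbert_tf(EpochArray(np.zeros(1920)), np.array([10.0, 50.0]))
        assert np.allclose(tf.amplitude, 0.0, atol=1e-10)

    def test_full_grid_has_98_bands(self):
        assert FREQ_GRID.size == 98
        tf = hilbert_tf(EpochArray(np.random.default_rng(0).standard_normal(1920)),
                        decimate=12)
        assert tf.amplitude.shape[1] == 98

    def test_reconstruction_from_amplitude_and_phase(self):
        """amplitude * cos(phase) reproduces the band-passed series."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal(1920)
        tf = hilbert_tf(EpochArray(x), np.array([20.0]), method="sos")
        recon = tf.amplitude[0, 0] * np.cos(tf.phase[0, 0])
        target = bandpass(x, 20)
        err = np.sqrt(np.mean((recon[MID] - target[MID]) ** 2))
        assert err < 0.01 * np.sqrt(np.mean(target[MID] ** 2))

    def test_fft_and_sos_paths_agree_midband(self):
        rng = np.random.default_rng(4)
        ep = EpochArray(rng.standard_normal((8, 1920)))
        a = hilbert_tf(ep, np.array([20.0, 40.0, 71.0]), method="fft")
        b = hilbert_tf(ep, np.array([20.0, 40.0, 71.0]), method="sos")
        rel = (np.sqrt(np.mean((a.amplitude[..., MID] - b.amplitude[..., MID]) ** 2))
               / np.sqrt(np.mean(b.amplitude[..., MID] ** 2)))
        assert rel < 0.05

    def test_band_power_monotonicity(self):
        rng = np.random.default_rng(5)
        noise = rng.standard_normal(1920)
        base = hilbert_tf(EpochArray(noise), np.array([30.0]))
        boosted = hilbert_tf(EpochArray(noise + sinusoid(30, 2.0)), np.array([30.0]))
        assert boosted.amplitude[0, 0, MID].mean() > base.amplitude[0, 0, MID].mean()


def _const_tf(value, n_trials=3):
    amp = np.full((n_trials, 2, T.size), float(value))
    return TFDecomposition(amplitude=amp, phase=np.zeros_like(amp),
                           frequencies=np.array([10.0, 20.0]), times=T)


class TestBaselineAndWindows:
    def test_constant_amplitude_baselines_to_zero(self):
        out = apply_baseline(_const_tf(3.7))
        assert np.allclose(out.amplitude, 0.0)
        assert out.baselined

    def test_step_baseline_recovers_step_height(self):
        tf = _const_tf(1.0)
        tf.amplitude[:, :, T >= 0.03] += 0.9
        out = apply_baseline(tf)
        active = out.amplitude[:, :, T >= 0.1]
        assert active == pytest.approx(0.9, abs=1e-9)

    def test_baseline_window_outside_epoch_raises(self):
        with pytest.raises(ValueError):
            apply_baseline(_const_tf(1.0), baseline_window=(-2.0, -1.5))

    def test_window_mean_amplitude_cases(self):
        tf = _const_tf(2.0)
        assert window_mean_amplitude(tf, (0.1, 0.4), 10)[0] == pytest.approx(2.0)
        # single-sample window
        one = window_mean_amplitude(tf, (0.0, 1 / 2400), 20)
        assert one[0] == pytest.approx(2.0)
        # linear ramp over the window averages to its midpoint
        ramp = _const_tf(0.0)
        w = (0.0, 0.5)
        sel = (T >= w[0]) & (T <= w[1])
        ramp.amplitude[:, 0, sel] = np.linspace(0, 1, sel.sum())
        assert window_mean_amplitude(ramp, w, 10)[0] == pytest.approx(0.5, abs=2 / 1200)

    def test_entrainment_window_28hz(self):
        active, base = entrainment_windows(28, 0.5)
        dur = active[1] - active[0]
        assert dur * 1000 == pytest.approx(6.5 / 28 * 1000 + 200, abs=0.1)
        assert base[1] == pytest.approx(active[0] - 0.05)
        assert (base[1] - base[0]) == pytest.approx(dur)

    def test_entrainment_window_capped_at_800ms(self):
        active, base = entrainment_windows(6, 0.5)
        assert (active[1] - active[0]) == pytest.approx(0.8)

    @pytest.mark.parametrize("freq", [3, 4, 6, 8, 10, 12, 14, 16, 18, 22, 28, 38])
    def test_baseline_duration_equals_active(self, freq):
        for bounds in (None, (-0.8, 0.799)):
            active, base = entrainment_windows(freq, 0.5, epoch_bounds=bounds)
            assert (base[1] - base[0]) == pytest.approx(active[1] - active[0])
            if bounds is not None:
                assert base[0] >= bounds[0] - 1e-9
                assert active[1] <= bounds[1] + 1e-9
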