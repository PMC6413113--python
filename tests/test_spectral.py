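"""Band-power extraction against an independent naive-DFT oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pmsfe import (
    ALPHA,
    BETA,
    THETA,
    BandPowerSet,
    FrequencyBand,
    TrialRecording,
    center_spectra,
    compute_band_power,
    extract_band_power_set,
)


def naive_band_power(signal: np.ndarray, fs: float, low: float, high: float) -> np.ndarray:
    """O(N^2) full-DFT summation: sum |X(k)|^2 over bins with low <= f_k < high."""
    signal = np.atleast_2d(signal)
    n = signal.shape[1]
    k = np.arange(n)
    dft = np.exp(-2j * np.pi * np.outer(k, k) / n)
    spectrum = signal @ dft.T
    freqs = k * fs / n
    mask = (freqs >= low) & (freqs < high) & (freqs > 0)
    return np.sum(np.abs(spectrum[:, mask]) ** 2, axis=1)


def make_trial(signal, fs=500.0, subject=1, level=1, trial_id=1):
    signal = np.atleast_2d(signal)
    if signal.shape[0] == 1:
        signal = np.tile(signal, (1, 1))
    return TrialRecording(signal=signal, fs=fs, subject_id=subject,
                          load_level=level, trial_id=trial_id)


def make_trial64(signal_row, fs=500.0):
    sig = np.tile(np.atleast_2d(signal_row), (64, 1))
    return TrialRecording(signal=sig, fs=fs, subject_id=1, load_level=1, trial_id=1)


class TestComputeBandPower:
    def test_zero_signal_gives_zero_power(self):
        trial = make_trial(np.zeros((3, 1000)))
        for band in (THETA, ALPHA, BETA):
            assert np.all(compute_band_power(trial, band) == 0)

    def test_pure_alpha_sinusoid_matches_oracle_and_leaks_nothing(self):
        # 10 Hz, 3.5 s at 500 Hz: integer number of cycles, rect window
        fs, dur = 500.0, 3.5
        t = np.arange(int(fs * dur)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        trial = make_trial(x, fs=fs)
        alpha = compute_band_power(trial, ALPHA)[0]
        expected = naive_band_power(x, fs, ALPHA.low_hz, ALPHA.high_hz)[0]
        assert alpha == pytest.approx(expected, rel=1e-10)
        assert alpha > 0
        assert compute_band_power(trial, THETA)[0] <= 1e-6 * alpha
        assert compute_band_power(trial, BETA)[0] <= 1e-6 * alpha

    def test_two_tone_powers_separate_into_their_bands(self):
        fs, dur = 500.0, 2.0
        t = np.arange(int(fs * dur)) / fs
        x5 = 1.3 * np.sin(2 * np.pi * 5.0 * t + 0.2)
        x20 = 0.7 * np.sin(2 * np.pi * 20.0 * t + 1.1)
        both = make_trial(x5 + x20, fs=fs)
        theta = compute_band_power(both, THETA)[0]
        beta = compute_band_power(both, BETA)[0]
        assert theta == pytest.approx(
            naive_band_power(x5, fs, THETA.low_hz, THETA.high_hz)[0], rel=1e-8
        )
        assert beta == pytest.approx(
            naive_band_power(x20, fs, BETA.low_hz, BETA.high_hz)[0], rel=1e-8
        )

    @pytest.mark.parametrize("window", ["rect", "hann"])
    def test_random_signals_match_oracle(self, window, rng):
        for _ in range(10):
            n = int(rng.integers(300, 1200))
            fs = float(rng.uniform(80, 500))
            x = rng.normal(size=(2, n))
            if window == "hann":
                xw = x * np.hanning(n)
            else:
                xw = x
            trial = make_trial(x, fs=fs)
            for band in (THETA, ALPHA, BETA):
                if band.high_hz > fs / 2:
                    continue
                got = compute_band_power(trial, band, window=window)
                want = naive_band_power(xw, fs, band.low_hz, band.high_hz)
                np.testing.assert_allclose(got, want, rtol=1e-8, atol=1e-12)

    def test_band_above_nyquist_rejected(self):
        trial = make_trial(np.random.default_rng(0).normal(size=(1, 400)), fs=50.0)
        with pytest.raises(ValueError, match="Nyquist"):
            compute_band_power(trial, BETA)

    def test_power_nonnegative_and_scales_quadratically(self, rng):
        x = rng.normal(size=(4, 700))
        trial = make_trial(x)
        base = compute_band_power(trial, ALPHA)
        assert np.all(base >= 0)
        for c in (0.5, 3.0, 10.0):
            scaled = compute_band_power(make_trial(c * x), ALPHA)
            np.testing.assert_allclose(scaled, c**2 * base, rtol=1e-10)

    def test_invalid_band_definition_rejected(self):
        with pytest.raises(ValueError):
            FrequencyBand("bad", 10.0, 4.0)


class TestExtractBandPowerSet:
    def test_zero_trial_gives_zero_set_with_right_shapes(self):
        trial = make_trial(np.zeros((64, 500)))
        s = extract_band_power_set(trial)
        for vec in (s.theta, s.alpha, s.beta):
            assert len(vec) == 64
            assert np.all(vec == 0)

    def test_wrong_electrode_count_is_an_error(self):
        trial = make_trial(np.zeros((32, 500)))
        with pytest.raises(ValueError, match="64"):
            extract_band_power_set(trial)

    def test_alpha_oscillation_shows_only_on_its_electrode_and_band(self):
        fs = 500.0
        t = np.arange(int(3.5 * fs)) / fs
        sig = np.zeros((64, len(t)))
        sig[7] = np.sin(2 * np.pi * 10.0 * t)  # electrode index 8, 1-based
        s = extract_band_power_set(make_trial(sig, fs=fs))
        assert s.alpha[7] > 0
        assert s.theta[7] == pytest.approx(0, abs=1e-6 * s.alpha[7])
        assert np.all(s.alpha[np.arange(64) != 7] < 1e-9 * s.alpha[7])


class TestCenterSpectra:
    @staticmethod
    def _sets(values_per_trial):
        out = []
        for i, v in enumerate(values_per_trial, start=1):
            arr = np.full(64, float(v))
            out.append(BandPowerSet(theta=arr, alpha=arr + 1, beta=arr + 2, trial_id=i))
        return out

    def test_none_mode_is_identity(self):
        sets = self._sets([3.0, 5.0])
        out = center_spectra(sets, mode="none")
        for a, b in zip(sets, out):
            np.testing.assert_array_equal(a.values(), b.values())

    def test_constant_single_trial_centers_to_zero(self):
        arr = np.full(64, 7.5)
        s = BandPowerSet(theta=arr, alpha=arr, beta=arr, trial_id=1)
        (out,) = center_spectra([s], mode="dataset_mean")
        np.testing.assert_allclose(out.values(), 0.0, atol=1e-12)

    def test_dataset_mean_matches_hand_computed_scalar(self):
        sets = self._sets([0.0, 6.0])
        # grand mean: mean over {0,1,2} and {6,7,8} blocks = 4.0
        out = center_spectra(sets, mode="dataset_mean")
        np.testing.assert_allclose(out[0].theta, -4.0)
        np.testing.assert_allclose(out[1].beta, 4.0)
        grand = np.mean(np.concatenate([o.values() for o in out]))
        assert abs(grand) < 1e-10

    def test_trial_mean_zeroes_each_trial(self):
        sets = self._sets([2.0, 9.0])
        out = center_spectra(sets, mode="trial_mean")
        for o in out:
            assert abs(np.mean(o.values())) < 1e-12

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            center_spectra([], mode="none")


@settings(max_examples=25, deadline=None)
@given(
    scale=st.floats(min_value=0.01, max_value=50.0),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_band_power_quadratic_scaling_property(scale, seed):
    """Scaling the signal by c scales every band power by c^2 (rect window)."""
    g = np.random.default_rng(seed)
    x = g.normal(size=(1, 512))
    base = compute_band_power(make_trial(x), ALPHA)
    scaled = compute_band_power(make_trial(scale * x), ALPHA)
    np.testing.assert_allclose(scaled, scale**2 * base, rtol=1e-9, atol=1e-30)
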