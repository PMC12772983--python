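"""Feature definitions against analytic values and brute-force oracles."""

import numpy as np
import pytest
from scipy import signal as sp_signal

from ehgtrends import (
    AnalysisWindow,
    hilbert_envelope_kurtosis,
    median_frequency,
    peak_to_peak,
    sample_entropy,
    summarize_recording,
    window_features,
)
from ehgtrends.features import WindowFeatures

from _oracles import median_frequency_line_spectrum, sampen_bruteforce

FS = 20.0


def window(x, start_s=0.0):
    return AnalysisWindow(np.asarray(x, float), FS, start_s)


def tone(freq, n=2400, amp=1.0, phase=0.0):
    t = np.arange(n) / FS
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestPeakToPeak:
    def test_unit_sinusoid(self):
        # quarter-period phase puts samples exactly on the peaks
        assert peak_to_peak(window(tone(0.5, phase=np.pi / 2))) == pytest.approx(2.0, abs=1e-6)

    def test_constant_and_small(self):
        assert peak_to_peak(window(np.ones(100))) == 0.0
        assert peak_to_peak(window([-3.0, 0.0, 5.0])) == 8.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            peak_to_peak(np.array([]))

    def test_scales_linearly(self):
        x = np.random.default_rng(0).standard_normal(500)
        assert peak_to_peak(window(3.0 * x)) == pytest.approx(3.0 * peak_to_peak(window(x)))


class TestEnvelopeKurtosis:
    def test_scale_invariance(self):
        x = np.random.default_rng(1).standard_normal(2400)
        assert hilbert_envelope_kurtosis(x, fs=FS) == pytest.approx(
            hilbert_envelope_kurtosis(250.0 * x, fs=FS), rel=1e-12
        )

    def test_constant_window_undefined(self):
        assert np.isnan(hilbert_envelope_kurtosis(np.zeros(2400), fs=FS))

    def test_bursty_exceeds_continuous(self):
        """A silent window with one burst is more impulsive than a steady tone."""
        steady = tone(0.5)
        bursty = np.zeros(2400)
        bursty[1100:1300] = tone(0.5, n=200) * np.hanning(200) * 10
        k_steady = hilbert_envelope_kurtosis(steady, fs=FS)
        k_bursty = hilbert_envelope_kurtosis(bursty, fs=FS)
        assert k_bursty > k_steady

    def test_gaussian_noise_near_rayleigh(self):
        """Envelope of band-limited Gaussian noise is Rayleigh; modest n check."""
        rayleigh_kurt = 3 + (24 * np.pi - 6 * np.pi**2 - 16) / (4 - np.pi) ** 2
        sos = sp_signal.butter(5, [0.1, 4.0], "bandpass", fs=FS, output="sos")
        vals = [
            hilbert_envelope_kurtosis(
                sp_signal.sosfiltfilt(sos, np.random.default_rng(s).standard_normal(2400)),
                fs=FS,
            )
            for s in range(50)
        ]
        assert np.mean(vals) == pytest.approx(rayleigh_kurt, abs=0.3)


class TestMedianFrequency:
    def test_pure_tone(self):
        bin_width = FS / 256
        assert median_frequency(tone(0.5), fs=FS) == pytest.approx(0.5, abs=bin_width)

    def test_two_tone_midpoint_matches_line_spectrum_oracle(self):
        expected = median_frequency_line_spectrum(
            np.array([0.3, 0.7]), np.array([1.0, 1.0]), (0.2, 1.0)
        )
        assert expected == pytest.approx(0.5)
        got = median_frequency(tone(0.3) + tone(0.7), fs=FS)
        assert got == pytest.approx(expected, abs=0.05)

    def test_out_of_band_line_ignored(self):
        bin_width = FS / 256
        got = median_frequency(tone(0.1) + tone(0.5), fs=FS)
        assert got == pytest.approx(0.5, abs=bin_width)

    def test_monotone_in_carrier(self):
        """Moving a narrowband burst's carrier from 0.3 to 0.7 Hz raises MDF."""
        rng = np.random.default_rng(5)
        noise = 0.01 * rng.standard_normal(2400)
        mdfs = [median_frequency(tone(f) + noise, fs=FS) for f in (0.3, 0.5, 0.7)]
        assert mdfs[0] < mdfs[1] < mdfs[2]

    def test_zero_power_undefined(self):
        assert np.isnan(median_frequency(np.zeros(2400), fs=FS))


class TestSampleEntropy:
    def test_alternating_sequence_is_zero(self):
        """Every length-2 match extends to length 3, so -ln(A/B) = 0."""
        x = np.tile([1.0, -1.0], 50)
        assert sample_entropy(x) == 0.0
        assert sampen_bruteforce(x) == 0.0

    def test_affine_invariance(self):
        x = np.random.default_rng(2).standard_normal(600)
        base = sample_entropy(x)
        assert sample_entropy(-2.5 * x + 17.0) == pytest.approx(base, rel=1e-12)

    @pytest.mark.parametrize("n,seed", [(200, 0), (600, 1), (1200, 2), (2400, 3)])
    def test_matches_bruteforce_oracle(self, n, seed):
        x = np.random.default_rng(seed).uniform(size=n)
        assert sample_entropy(x) == pytest.approx(sampen_bruteforce(x), abs=1e-12)

    def test_constant_undefined(self):
        assert np.isnan(sample_entropy(np.ones(100)))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sample_entropy(np.array([1.0, 2.0, 3.0]))

    def test_regularity_orders_entropy(self):
        """Less phase jitter in the generator means lower mean SampEn."""
        from ehgtrends import SignalSimConfig, preprocess_recording, simulate_recording

        sos = sp_signal.butter(5, [0.34, 4.0], "bandpass", fs=FS, output="sos")

        def mean_sampen(regularity):
            vals = []
            for s in range(4):
                cfg = SignalSimConfig(duration_s=480.0, seed=600 + s, regularity=regularity)
                wins = preprocess_recording(simulate_recording(cfg))
                vals += [
                    sample_entropy(sp_signal.sosfiltfilt(sos, w.samples)) for w in wins
                ]
            assert len(vals) >= 20
            return np.mean(vals)

        assert mean_sampen(0.1) > mean_sampen(0.9)


class TestAggregation:
    def make(self, ppa, khe=4.0, mdf=0.5, sampen=1.0, start=0.0):
        return WindowFeatures(ppa=ppa, khe=khe, mdf=mdf, sampen=sampen, start_s=start)

    def test_single_window_passthrough(self):
        s = summarize_recording([self.make(2.5)])
        assert (s.median_ppa, s.median_khe, s.n_windows) == (2.5, 4.0, 1)

    def test_median_robust_to_outlier(self):
        s = summarize_recording([self.make(1.0), self.make(2.0), self.make(100.0)])
        assert s.median_ppa == 2.0

    def test_permutation_invariant_and_bounded(self, rng):
        feats = [self.make(float(p)) for p in rng.uniform(0, 10, size=9)]
        shuffled = [feats[i] for i in rng.permutation(9)]
        s1, s2 = summarize_recording(feats), summarize_recording(shuffled)
        assert s1.median_ppa == s2.median_ppa
        ppas = [f.ppa for f in feats]
        assert min(ppas) <= s1.median_ppa <= max(ppas)

    def test_nan_windows_excluded_per_feature(self):
        feats = [self.make(1.0, sampen=float("nan")), self.make(3.0, sampen=2.0)]
        s = summarize_recording(feats)
        assert s.median_ppa == 2.0
        assert s.median_sampen == 2.0

    def test_zero_windows_rejected(self):
        with pytest.raises(ValueError):
            summarize_recording([])


def test_window_features_returns_all_four():
    rng = np.random.default_rng(9)
    sos = sp_signal.butter(5, [0.1, 4.0], "bandpass", fs=FS, output="sos")
    w = window(sp_signal.sosfiltfilt(sos, rng.standard_normal(2400)))
    f = window_features(w)
    assert f.ppa > 0
    assert not np.isnan(f.khe)
    assert 0.2 <= f.mdf <= 1.0
    assert f.sampen > 0
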