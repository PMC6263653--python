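"""STFT, periodogram, band powers and dB baseline normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from eegskill.montage import BANDS
from eegskill.recording import EEGRecording
from eegskill.spectral import (
    Spectrum,
    averaged_periodogram,
    band_powers,
    db_normalize,
    normalize_periodogram,
    periodogram,
    spectral_feature_row,
    stft,
)

FS = 128.0


class TestSTFT:
    def test_segment_count_half_overlap(self, rng):
        freqs, Z = stft(rng.normal(size=1024), FS, window_length=256, overlap=0.5)
        assert Z.shape[0] == (1024 - 256) // 128 + 1 == 7

    def test_segment_count_no_overlap(self, rng):
        _, Z = stft(rng.normal(size=1024), FS, window_length=256, overlap=0.0)
        assert Z.shape[0] == 4

    def test_tone_peaks_at_analytic_bin(self):
        x = np.sin(2 * np.pi * 10.0 * np.arange(1024) / FS)
        freqs, Z = stft(x, FS, window_length=256)
        peak_bins = np.abs(Z).argmax(axis=1)
        assert (peak_bins == 20).all()  # 10 Hz at 0.5 Hz resolution
        assert freqs[20] == pytest.approx(10.0)

    def test_window_longer_than_signal_names_minimum(self, rng):
        with pytest.raises(ValueError, match="256"):
            stft(rng.normal(size=100), FS, window_length=256)


class TestPeriodogram:
    def test_zero_signal_zero_power(self):
        Z = np.fft.fft(np.zeros(64))
        assert periodogram(Z, 64).sum() == 0

    def test_parseval_on_untapered_segment(self, rng):
        x = rng.normal(size=64)
        per = periodogram(np.fft.fft(x), 64)
        assert per.sum() == pytest.approx(np.sum(x**2), rel=1e-9)

    def test_amplitude_doubling_quadruples_power(self, rng):
        x = rng.normal(size=64)
        p1 = periodogram(np.fft.fft(x), 64)
        p2 = periodogram(np.fft.fft(2 * x), 64)
        assert p2 == pytest.approx(4 * p1, rel=1e-12)

    def test_matches_textbook_welch_estimate(self, rng):
        # dual route: averaged Hann periodogram vs scipy.signal.welch
        x = rng.normal(size=int(10 * FS))
        mine = averaged_periodogram(x, FS, window_length=256, overlap=0.5)
        win = np.hanning(256)
        f_ref, p_ref = sps.welch(
            x, FS, window=win, nperseg=256, noverlap=128, detrend=False,
            scaling="spectrum", return_onesided=True,
        )
        # welch 'spectrum' scaling: |fft|^2 / sum(win)^2, doubled off DC/Nyquist
        conv = p_ref * (win.sum() ** 2) / 256.0
        conv[1:-1] /= 2.0
        assert np.allclose(mine.power, conv, rtol=1e-6)
        assert np.allclose(mine.frequencies, f_ref)


class TestNormalize:
    def test_sums_to_one(self, rng):
        p = averaged_periodogram(rng.normal(size=2048), FS)
        q = normalize_periodogram(p)
        assert q.power.sum() == pytest.approx(1.0, abs=1e-9)

    def test_two_bin_example(self):
        p = Spectrum(np.array([0.0, 1.0]), np.array([3.0, 1.0]))
        q = normalize_periodogram(p)
        assert q.power.tolist() == [0.75, 0.25]

    def test_idempotent(self, rng):
        p = averaged_periodogram(rng.normal(size=2048), FS)
        q1 = normalize_periodogram(p)
        q2 = normalize_periodogram(q1)
        assert np.allclose(q1.power, q2.power, atol=1e-15)

    def test_zero_spectrum_rejected(self):
        with pytest.raises(ValueError):
            normalize_periodogram(Spectrum(np.array([0.0, 1.0]), np.zeros(2)))


class TestBandPowers:
    def test_pure_alpha_tone(self):
        x = np.sin(2 * np.pi * 10.0 * np.arange(int(20 * FS)) / FS)
        bp = band_powers(averaged_periodogram(x, FS))
        assert bp["alpha"] >= 0.95
        assert bp["theta"] + bp["beta"] + bp["gamma"] <= 0.05

    def test_white_noise_powers_proportional_to_bandwidth(self, rng):
        x = rng.normal(size=100_000)
        bp = band_powers(averaged_periodogram(x, FS))
        for name, (low, high) in BANDS.items():
            expected = (min(high, 43.0) - low) / 43.0
            assert bp[name] == pytest.approx(expected, rel=0.10)

    def test_gamma_clipped_at_43(self, rng):
        x = rng.normal(size=8192)
        p = averaged_periodogram(x, FS)
        bp = band_powers(p)
        sel = (p.frequencies >= 30) & (p.frequencies < 43)
        total = p.power[p.frequencies < 43].sum()
        assert bp["gamma"] == pytest.approx(p.power[sel].sum() / total, rel=1e-12)

    def test_band_outside_range_rejected(self, rng):
        p = averaged_periodogram(rng.normal(size=1024), FS)
        with pytest.raises(ValueError):
            band_powers(p, bands={"hf": (70.0, 90.0)})

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_relative_powers_always_unit_interval(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=1024) * r.uniform(0.01, 100)
        bp = band_powers(averaged_periodogram(x, FS))
        four = [bp[b] for b in BANDS]
        assert all(0 <= v <= 1 for v in four)
        assert sum(four) <= 1 + 1e-9


class TestDbNormalize:
    @pytest.mark.parametrize("ratio,expected", [(1.0, 0.0), (10.0, 10.0), (2.0, 10 * np.log10(2))])
    def test_reference_ratios(self, ratio, expected):
        assert db_normalize(ratio * 5.0, 5.0) == pytest.approx(expected, abs=1e-12)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            db_normalize(1.0, 0.0)

    def test_negative_activity_rejected(self):
        with pytest.raises(ValueError):
            db_normalize(-1.0, 1.0)


class TestFeatureRow:
    def _rec(self, data, span):
        labels = tuple(f"C{i}" for i in range(data.shape[0]))
        return EEGRecording(data=data, fs=FS, channel_labels=labels, baseline_span=span)

    def test_seventy_features_for_full_montage(self, sim_recording):
        from eegskill.preprocessing import split_baseline

        base, task = split_baseline(sim_recording)
        row = spectral_feature_row(task, base)
        assert len(row) == 70

    def test_identical_segments_give_zero_db(self, rng):
        x = rng.normal(size=(2, 2048))
        seg = self._rec(x, (0, 0))
        row = spectral_feature_row(seg, seg)
        assert np.allclose(row.to_numpy(), 0.0, atol=1e-12)

    def test_planted_theta_tripling_reads_4_77_db(self, rng):
        # amplify the 4-8 Hz content of the task segment by sqrt(3) in the
        # frequency domain; the theta dB feature must read 10 log10(3)
        n = 8192
        x = rng.normal(size=n)
        spec = np.fft.rfft(x)
        freqs = np.fft.rfftfreq(n, 1 / FS)
        boosted = spec.copy()
        boosted[(freqs >= 4) & (freqs < 8)] *= np.sqrt(3.0)
        task = np.fft.irfft(boosted, n=n)[None, :]
        base = x[None, :]
        row = spectral_feature_row(self._rec(task, (0, 0)), self._rec(base, (0, 0)))
        assert row["C0_theta_db"] == pytest.approx(10 * np.log10(3), abs=0.3)

    def test_include_both_concatenates_db_and_relative_sets(self, rng):
        x = rng.normal(size=(1, 2048))
        seg = self._rec(x, (0, 0))
        row = spectral_feature_row(seg, seg, include_both=True)
        assert len(row) == 10
        assert sum(n.endswith("_rel") for n in row.index) == 5

    def test_short_baseline_rejected(self, rng):
        task = self._rec(rng.normal(size=(1, 2048)), (0, 0))
        base = self._rec(rng.normal(size=(1, 100)), (0, 0))
        with pytest.raises(ValueError, match="window"):
            spectral_feature_row(task, base)
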