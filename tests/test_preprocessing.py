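"""DC removal, outlier rejection and baseline segmentation."""

import numpy as np
import pytest

from eegskill.preprocessing import (
    preprocess_variant,
    remove_dc,
    remove_outliers,
    split_baseline,
)
from eegskill.recording import EEGRecording


def _rec(data, fs=128.0, span=(0, 0), labels=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    labels = labels or tuple(f"C{i}" for i in range(data.shape[0]))
    return EEGRecording(data=data, fs=fs, channel_labels=labels, baseline_span=span)


class TestRemoveDC:
    def test_constant_channel_driven_to_zero(self):
        # time constant is ~1 s (0.16 Hz cutoff); a 50 uV step has decayed
        # below 1e-3 uV after ~11 time constants
        rec = _rec(np.full((2, 128 * 20), 50.0))
        out = remove_dc(rec)
        settled = out.data[:, 128 * 15:]
        assert np.abs(settled).max() < 1e-3

    def test_sinusoid_amplitude_preserved_and_mean_removed(self):
        # x[n] = 50 + 10 sin(2 pi 10 n / 128); least-squares sinusoid fit
        n = np.arange(128 * 30)
        x = 50.0 + 10.0 * np.sin(2 * np.pi * 10.0 * n / 128.0)
        out = remove_dc(_rec(x)).data[0][128 * 15:]  # discard the DC transient
        t = n[128 * 15:]
        design = np.column_stack([
            np.sin(2 * np.pi * 10.0 * t / 128.0),
            np.cos(2 * np.pi * 10.0 * t / 128.0),
            np.ones_like(t),
        ])
        coef, *_ = np.linalg.lstsq(design, out, rcond=None)
        amplitude = np.hypot(coef[0], coef[1])
        assert amplitude == pytest.approx(10.0, rel=0.02)
        assert abs(coef[2]) < 0.1

    def test_ten_hz_attenuation_below_two_percent(self):
        n = np.arange(128 * 30)
        x = 10.0 * np.sin(2 * np.pi * 10.0 * n / 128.0)
        out = remove_dc(_rec(x)).data[0][128 * 2:]
        ratio = np.sqrt(np.mean(out**2)) / np.sqrt(np.mean(x[128 * 2:] ** 2))
        assert ratio > 0.98

    def test_near_idempotent_after_settling(self):
        # one-pole high-pass: a second pass changes content in the analysis
        # band only through the residual gain/phase at f >> 0.16 Hz (~fc/f),
        # so for a 20 Hz tone the paired difference is below 1% RMS
        n = np.arange(128 * 30)
        x = 10.0 * np.sin(2 * np.pi * 20.0 * n / 128.0)[None, :]
        once = remove_dc(_rec(x))
        twice = remove_dc(once)
        d = (twice.data - once.data)[:, 128 * 15:]
        rms_sig = np.sqrt(np.mean(once.data[:, 128 * 15:] ** 2))
        assert np.sqrt(np.mean(d**2)) < 0.01 * rms_sig

    def test_linearity(self, rng):
        x = rng.normal(size=(1, 1000))
        y = rng.normal(size=(1, 1000))
        lhs = remove_dc(_rec(2.0 * x + 3.0 * y)).data
        rhs = 2.0 * remove_dc(_rec(x)).data + 3.0 * remove_dc(_rec(y)).data
        assert np.sqrt(np.mean((lhs - rhs) ** 2)) < 1e-9

    def test_too_short_input(self):
        with pytest.raises(ValueError):
            remove_dc(_rec([[1.0]]))


class TestRemoveOutliers:
    def test_worked_five_sample_example(self):
        # mean |x| = 2.8, threshold 8.4 -> the 10 is dropped, fraction 0.2
        rec = _rec([1.0, 1.0, 1.0, 1.0, 10.0])
        out, report = remove_outliers(rec, k=3.0)
        assert out.data.tolist() == [[1.0, 1.0, 1.0, 1.0]]
        assert report.fraction_removed == pytest.approx(0.2)

    def test_clean_signal_untouched(self, rng):
        rec = _rec(rng.uniform(0.5, 1.5, size=(2, 500)))
        out, report = remove_outliers(rec)
        assert np.array_equal(out.data, rec.data)
        assert report.fraction_removed == 0.0

    def test_large_k_is_identity(self, rng):
        rec = _rec(rng.normal(size=(2, 500)))
        out, _ = remove_outliers(rec, k=1e12)
        assert np.array_equal(out.data, rec.data)

    def test_retained_amplitudes_unaltered(self, rng):
        x = rng.normal(size=500)
        x[10] = 100.0
        rec = _rec(x)
        out, _ = remove_outliers(rec)
        kept = np.abs(rec.data[0]) <= 3 * np.abs(rec.data[0]).mean()
        assert np.array_equal(out.data[0], rec.data[0][kept])

    def test_cross_channel_drop_keeps_alignment(self):
        d = np.ones((2, 6))
        d[0, 2] = 50.0  # outlier only in channel 0
        out, _ = remove_outliers(_rec(d))
        assert out.data.shape == (2, 5)

    def test_baseline_span_reindexed(self):
        d = np.ones((1, 10))
        d[0, 3] = 100.0
        rec = _rec(d, span=(0, 6))
        out, _ = remove_outliers(rec)
        assert out.baseline_span == (0, 5)

    def test_zero_amplitude_channel_rejected(self):
        with pytest.raises(ValueError, match="zero mean absolute"):
            remove_outliers(_rec(np.zeros((1, 5))))

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            remove_outliers(_rec([1.0, 2.0, 3.0]), k=0)


class TestSplitBaseline:
    def test_36s_span_yields_4608_samples(self, sim_recording):
        base, task = split_baseline(sim_recording)
        assert base.n_samples == 4608
        assert task.baseline_span == (0, 0)

    def test_conservation_of_samples(self, sim_recording):
        base, task = split_baseline(sim_recording)
        assert base.n_samples + task.n_samples == sim_recording.n_samples
        recon = np.concatenate([base.data, task.data], axis=1)
        assert np.array_equal(recon, sim_recording.data)

    def test_empty_baseline_errors(self, rng):
        rec = _rec(rng.normal(size=(1, 100)), span=(0, 0))
        with pytest.raises(ValueError, match="empty"):
            split_baseline(rec)

    def test_whole_recording_span_errors(self, rng):
        rec = _rec(rng.normal(size=(1, 100)), span=(0, 100))
        with pytest.raises(ValueError, match="task"):
            split_baseline(rec)


class TestVariants:
    def test_raw_is_identity_with_zero_removed(self, sim_recording):
        out, report = preprocess_variant(sim_recording, "raw")
        assert np.array_equal(out.data, sim_recording.data)
        assert report.fraction_removed == 0.0

    def test_nodc_trims_settling_and_removes_offset(self, sim_recording):
        out, _ = preprocess_variant(sim_recording, "nodc")
        assert out.n_samples == sim_recording.n_samples - 128
        # DC offset (200 uV by default) must be gone
        assert abs(out.data.mean()) < 2.0

    def test_outliers_detected_on_dc_removed_data(self):
        # with a large DC offset the raw 3x-mean rule would flag nothing:
        # spikes of ~8x background RMS sit far below 3 x (offset-dominated mean)
        rng = np.random.default_rng(0)
        x = rng.normal(0, 10, size=128 * 10)
        x[::640] = 90.0  # spikes
        rec = _rec(x + 500.0, span=(0, 128))
        raw_flagged = (np.abs(rec.data) > 3 * np.abs(rec.data).mean()).sum()
        assert raw_flagged == 0
        out, report = preprocess_variant(rec, "nooutliers")
        assert report.fraction_removed > 0

    def test_unknown_variant_rejected(self, sim_recording):
        with pytest.raises(ValueError):
            preprocess_variant(sim_recording, "denoised")
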