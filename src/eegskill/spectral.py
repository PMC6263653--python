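"""Spectral feature extraction: STFT, periodogram, band powers, dB baseline.

The task and baseline segments of each channel are analyzed with a
Hann-windowed short-time Fourier transform (default 256-sample windows, 50%
overlap; 2 s and 0.5 Hz resolution at 128 Hz, so the 4 Hz theta edge falls
on a bin). Per segment the periodogram |FFT|^2 / N estimates the power
spectral density; segment periodograms are averaged over the whole segment
(the standard averaged-modified-periodogram estimate). Frequencies at or
above the 43 Hz analysis ceiling are excluded everywhere.

Five features per channel: the relative power of theta, alpha, beta and
gamma (fractions of the normalized periodogram over the analyzed range) and
the total average power. By default each is reported baseline-normalized in
decibels, 10*log10(task / baseline), which cancels the 1/f scaling and
subject-specific amplitude factors; the raw-relative variants are available
alongside. 5 x 14 channels = 70 features per subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import BANDS, MAX_ANALYZED_HZ
from .recording import EEGRecording

DEFAULT_WINDOW = 256
DEFAULT_OVERLAP = 0.5

#: Names of the five spectral features per channel.
SPECTRAL_FEATURES = ("theta", "alpha", "beta", "gamma", "total_power")


@dataclass
class Spectrum:
    """A frequency grid with per-frequency power values."""

    frequencies: np.ndarray
    power: np.ndarray
    normalization: str = "raw"  # or "relative"
    window_length: int = DEFAULT_WINDOW
    overlap: float = DEFAULT_OVERLAP

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.shape != self.power.shape:
            raise ValueError("frequencies and power must have the same shape")
        if np.any(self.power < -1e-12):
            raise ValueError("power values must be non-negative")
        if self.normalization not in ("raw", "relative"):
            raise ValueError("normalization must be 'raw' or 'relative'")


def stft(x, fs: float, window_length: int = DEFAULT_WINDOW, overlap: float = DEFAULT_OVERLAP):
    """Hann-windowed short-time Fourier transform of a 1-D series.

    Segments start every ``hop = window_length * (1 - overlap)`` samples;
    the segment count is ``floor((len(x) - window_length) / hop) + 1``.
    Returns ``(frequencies, Z)`` with ``Z`` complex of shape
    ``(n_segments, n_bins)`` on the one-sided rfft grid.
    """
    x = np.asarray(x, dtype=float)
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    if window_length < 2:
        raise ValueError("window_length must be >= 2")
    if x.size < window_length:
        raise ValueError(
            f"signal of {x.size} samples shorter than one window; "
            f"minimum length is {window_length} samples"
        )
    hop = max(int(round(window_length * (1 - overlap))), 1)
    n_seg = (x.size - window_length) // hop + 1
    win = np.hanning(window_length)
    starts = np.arange(n_seg) * hop
    segs = np.stack([x[s : s + window_length] * win for s in starts])
    freqs = np.fft.rfftfreq(window_length, 1.0 / fs)
    return freqs, np.fft.rfft(segs, axis=1)


def periodogram(segment_fft, n_samples: int) -> np.ndarray:
    """Periodogram PSD estimate per(w) = |FFT(w)|^2 / N of one segment.

    Works on any FFT grid (one- or two-sided); on the full two-sided grid of
    an untapered segment the bin sum equals the time-domain energy sum
    (Parseval).
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    return np.abs(np.asarray(segment_fft)) ** 2 / n_samples


def averaged_periodogram(
    x, fs: float, window_length: int = DEFAULT_WINDOW, overlap: float = DEFAULT_OVERLAP
) -> Spectrum:
    """Segment-averaged Hann periodogram of a series, as a :class:`Spectrum`."""
    freqs, Z = stft(x, fs, window_length, overlap)
    per = periodogram(Z, window_length).mean(axis=0)
    return Spectrum(freqs, per, "raw", window_length, overlap)


def normalize_periodogram(p: Spectrum) -> Spectrum:
    """Scale a spectrum so its bins sum to 1 (relative contributions)."""
    total = float(p.power.sum())
    if total <= 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return Spectrum(p.frequencies, p.power / total, "relative", p.window_length, p.overlap)


def _band_slice(freqs, low, high, max_freq):
    return (freqs >= low) & (freqs < min(high, max_freq))


def band_powers(p: Spectrum, bands: dict = None, max_freq: float = MAX_ANALYZED_HZ) -> dict:
    """Relative band powers and total average power of a raw spectrum.

    Band powers are sums of the normalized periodogram over the half-open
    ``[low, high)`` bin ranges, normalization taken over the analyzed range
    ``[0, max_freq)`` only; the total average power is the mean raw
    periodogram value over that range.
    """
    bands = bands if bands is not None else BANDS
    if p.normalization != "raw":
        raise ValueError("band_powers expects a raw spectrum")
    fs_half = p.frequencies.max()
    for name, (low, high) in bands.items():
        if low < 0 or low >= high:
            raise ValueError(f"band {name} has invalid range [{low}, {high})")
        if low > fs_half:
            raise ValueError(f"band {name} lies outside [0, {fs_half}] Hz")
    analyzed = p.frequencies < max_freq
    total = float(p.power[analyzed].sum())
    if total <= 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    out = {}
    for name, (low, high) in bands.items():
        sel = _band_slice(p.frequencies, low, high, max_freq)
        out[name] = float(p.power[sel].sum()) / total
    out["total_power"] = float(p.power[analyzed].mean())
    return out


def db_normalize(activity_power, baseline_power):
    """Decibel change of activity power relative to baseline power.

    ``10 * log10(activity / baseline)`` elementwise; the baseline power at a
    frequency (or band) is the mean periodogram over the baseline segments.
    """
    activity = np.asarray(activity_power, dtype=float)
    baseline = np.asarray(baseline_power, dtype=float)
    if np.any(baseline <= 0):
        raise ValueError("baseline power must be strictly positive")
    if np.any(activity < 0):
        raise ValueError("activity power must be non-negative")
    out = 10.0 * np.log10(activity / baseline)
    return float(out) if out.ndim == 0 else out


def _raw_band_sums(p: Spectrum, bands, max_freq):
    sums = {
        name: float(p.power[_band_slice(p.frequencies, low, high, max_freq)].sum())
        for name, (low, high) in bands.items()
    }
    sums["total_power"] = float(p.power[p.frequencies < max_freq].mean())
    return sums


def spectral_feature_row(
    task: EEGRecording,
    baseline: EEGRecording,
    window_length: int = DEFAULT_WINDOW,
    overlap: float = DEFAULT_OVERLAP,
    bands: dict = None,
    max_freq: float = MAX_ANALYZED_HZ,
    normalize_db: bool = True,
    include_both: bool = False,
) -> pd.Series:
    """The five spectral features per channel for one subject.

    Both segments must have been preprocessed identically. With
    ``normalize_db`` (the default) each feature is the dB change of the task
    segment's band (or total) power relative to the baseline segment's,
    named ``{channel}_{feature}_db``; otherwise the task segment's relative
    band powers and total average power are returned, named
    ``{channel}_{feature}_rel``. ``include_both`` concatenates the two sets
    (140 entries). The default set has 5 x n_channels entries (70 for the
    full montage).
    """
    bands = bands if bands is not None else BANDS
    if task.channel_labels != baseline.channel_labels or task.fs != baseline.fs:
        raise ValueError("task and baseline segments do not match")
    if baseline.n_samples < window_length:
        raise ValueError(
            f"baseline of {baseline.n_samples} samples shorter than one "
            f"{window_length}-sample window"
        )
    db_vals, db_names, rel_vals, rel_names = [], [], [], []
    for ch, label in enumerate(task.channel_labels):
        p_task = averaged_periodogram(task.data[ch], task.fs, window_length, overlap)
        p_base = averaged_periodogram(baseline.data[ch], baseline.fs, window_length, overlap)
        rel = band_powers(p_task, bands, max_freq)
        s_task = _raw_band_sums(p_task, bands, max_freq)
        s_base = _raw_band_sums(p_base, bands, max_freq)
        for feat in list(bands) + ["total_power"]:
            rel_names.append(f"{label}_{feat}_rel")
            rel_vals.append(rel[feat])
            db_names.append(f"{label}_{feat}_db")
            db_vals.append(db_normalize(s_task[feat], s_base[feat]))
    if include_both:
        return pd.Series(db_vals + rel_vals, index=db_names + rel_names, name=task.subject_id)
    if normalize_db:
        return pd.Series(db_vals, index=db_names, name=task.subject_id)
    return pd.Series(rel_vals, index=rel_names, name=task.subject_id)
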