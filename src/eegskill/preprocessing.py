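"""Basic EEG preprocessing: DC removal, outlier rejection, segmentation.

Three data variants are produced, mirroring the analysis protocol:

* ``raw`` — untouched amplitudes;
* ``nodc`` — DC offset removed with a first-order high-pass whose -3 dB
  point is 0.16 Hz;
* ``nooutliers`` — DC removal followed by rejection of time points whose
  amplitude exceeds 3x the channel's mean absolute amplitude.

Outlier rejection always operates on DC-removed data: on a signal with a
large constant offset the raw mean absolute amplitude is dominated by the
offset and the 3x rule would flag nothing (or, for zero-mean signals and a
signed mean, everything).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .recording import EEGRecording

VARIANTS = ("raw", "nodc", "nooutliers")

#: -3 dB cutoff of the DC-removal high-pass, Hz.
DC_CUTOFF_HZ = 0.16

#: Seconds excluded from the start of the recording after DC filtering, so
#: the filter's step-response transient never enters feature windows.
SETTLE_S = 1.0


@dataclass
class PreprocessReport:
    """Bookkeeping for one preprocessing run."""

    variant: str
    fraction_removed: float = 0.0
    per_channel_flagged: tuple = ()

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if not 0.0 <= self.fraction_removed <= 1.0:
            raise ValueError("fraction_removed must lie in [0, 1]")
        if self.variant == "raw" and self.fraction_removed != 0:
            raise ValueError("raw variant cannot remove samples")


def remove_dc(rec: EEGRecording) -> EEGRecording:
    """Remove the DC offset with a one-pole leaky high-pass.

    The filter is ``y[n] = x[n] - x[n-1] + a * y[n-1]`` with ``a`` chosen so
    the -3 dB point sits at 0.16 Hz. A literal first-order (2-tap) FIR cannot
    realize a 0.16 Hz cutoff at fs = 128 — its first null is at fs/2 — so the
    standard leaky-differentiator form used by headset firmware is adopted;
    it rejects DC exactly and attenuates content above 1 Hz by far less than
    1 dB. The filter is linear and time-invariant.
    """
    if rec.n_samples < 2:
        raise ValueError("need at least 2 samples to high-pass filter")
    a = float(np.exp(-2.0 * np.pi * DC_CUTOFF_HZ / rec.fs))
    y = sps.lfilter([1.0, -1.0], [1.0, -a], rec.data, axis=1)
    return rec.with_data(y)


def remove_outliers(rec: EEGRecording, k: float = 3.0):
    """Drop time points whose amplitude exceeds ``k`` x mean |amplitude|.

    The threshold is computed per channel on the input's absolute
    amplitudes. A time index flagged in any channel is dropped in every
    channel so the matrix stays rectangular for windowed spectral analysis.
    The recording's baseline span is re-indexed to the retained samples.

    Returns ``(cleaned_recording, PreprocessReport)``.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    absx = np.abs(rec.data)
    mean_abs = absx.mean(axis=1)
    if np.any(mean_abs == 0):
        bad = rec.channel_labels[int(np.argmin(mean_abs))]
        raise ValueError(f"channel {bad} has zero mean absolute amplitude")
    flagged = absx > (k * mean_abs)[:, None]
    drop = flagged.any(axis=0)
    if drop.all():
        raise ValueError("all samples flagged as outliers; degenerate input")
    keep = ~drop
    start, end = rec.baseline_span
    new_span = (int(keep[:start].sum()), int(keep[:end].sum()))
    report = PreprocessReport(
        variant="nooutliers",
        fraction_removed=float(drop.mean()),
        per_channel_flagged=tuple(flagged.mean(axis=1)),
    )
    return rec.with_data(rec.data[:, keep], baseline_span=new_span), report


def split_baseline(rec: EEGRecording):
    """Split a recording into its resting-baseline and task segments.

    Concatenating the two segments (baseline first for a leading span)
    reconstructs the input. The task segment carries an empty baseline span.
    """
    start, end = rec.baseline_span
    if end <= start:
        raise ValueError("recording has an empty baseline_span")
    base = rec.with_data(rec.data[:, start:end], baseline_span=(0, end - start))
    task_data = np.concatenate([rec.data[:, :start], rec.data[:, end:]], axis=1)
    if task_data.shape[1] == 0:
        raise ValueError("baseline span covers the whole recording; no task segment")
    task = rec.with_data(task_data, baseline_span=(0, 0))
    return base, task


def preprocess_variant(rec: EEGRecording, variant: str, k: float = 3.0):
    """Apply one of the three preprocessing variants.

    ``raw`` copies the input. ``nodc`` applies :func:`remove_dc` and trims
    the first :data:`SETTLE_S` seconds (re-indexing the baseline span).
    ``nooutliers`` additionally applies :func:`remove_outliers` — always on
    the DC-removed data.

    Returns ``(recording, PreprocessReport)``.
    """
    variant = variant.lower()
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    if variant == "raw":
        return rec.copy(), PreprocessReport(variant="raw")
    filtered = remove_dc(rec)
    n_settle = int(round(SETTLE_S * rec.fs))
    if n_settle >= filtered.n_samples:
        raise ValueError("recording shorter than the filter settling window")
    start, end = filtered.baseline_span
    span = (max(start - n_settle, 0), max(end - n_settle, 0))
    trimmed = filtered.with_data(filtered.data[:, n_settle:], baseline_span=span)
    if variant == "nodc":
        return trimmed, PreprocessReport(variant="nodc")
    return remove_outliers(trimmed, k=k)
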