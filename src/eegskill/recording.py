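"""In-memory container for a multichannel EEG recording."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class EEGRecording:
    """A channels x samples EEG matrix with its acquisition metadata.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Amplitudes in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : tuple of str
        Unique channel names, one per row of ``data``.
    baseline_span : (int, int)
        Half-open ``[start, end)`` sample range of the resting baseline.
        ``(0, 0)`` means the recording carries no baseline (e.g. a task
        segment produced by :func:`~eegskill.preprocessing.split_baseline`).
    subject_id : str
        Identifier used to join recordings with score records.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple = field(default_factory=tuple)
    baseline_span: tuple = (0, 0)
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite amplitudes")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.n_channels} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        start, end = self.baseline_span
        if not (0 <= start <= end <= self.n_samples):
            raise ValueError(
                f"baseline_span {self.baseline_span} outside [0, {self.n_samples}]"
            )
        self.baseline_span = (int(start), int(end))

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray, baseline_span=None) -> "EEGRecording":
        """Copy of the recording with replaced samples (and optionally span)."""
        span = self.baseline_span if baseline_span is None else baseline_span
        return replace(self, data=np.asarray(data, dtype=float), baseline_span=span)

    def copy(self) -> "EEGRecording":
        return self.with_data(self.data.copy())
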