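"""Montage and analysis constants for the 14-channel consumer headset."""

#: 10-20 system electrode labels of the 14 recording channels, in device order.
CHANNELS = (
    "AF3", "AF4", "F3", "F4", "FC5", "FC6", "F7",
    "F8", "T7", "T8", "P7", "P8", "O1", "O2",
)

#: Sampling rate of the headset, samples per second.
FS = 128.0

#: Nominal frequency bands (Hz), half-open [low, high).
#: Shared edges belong to the upper band (8 Hz is alpha, not theta).
BANDS = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 60.0),
}

#: The headset's anti-aliasing low-pass already attenuates content from 43 Hz
#: upward, so spectral analysis is truncated there: bins at or above this
#: frequency are excluded from band and total-power sums (gamma is effectively
#: 30-43 Hz even though its nominal definition extends to 60 Hz).
MAX_ANALYZED_HZ = 43.0

#: Resting-period length recorded before the task (15 s eyes open, 15 s eyes
#: closed, plus 6 s of getting ready), used as the baseline for dB
#: normalization.
BASELINE_S = 36.0
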