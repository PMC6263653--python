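"""Synthetic EEG cohorts with planted, class-dependent band-power effects.

The generator emulates the statistical structure the downstream analysis
relies on, not physiological EEG morphology: a 1/f-scaled broadband
background band-limited below the 43 Hz analysis ceiling, band-limited
oscillatory components whose amplitudes are modulated by the subject's class
label for each cognitive skill, a constant acquisition DC offset,
Poisson-placed spike artifacts that deterministically trip the 3x-mean
amplitude outlier rule, and a 36 s resting baseline whose oscillations are
class-independent (so baseline-normalized spectral features carry the class
signal). Cognitive scores on the 0-800 scale are drawn either balanced
across the three levels (the default for cross-validated effect-recovery
experiments) or from bounded skewed families reproducing the positively
skewed focused-attention and negatively skewed working-memory score
distributions of the study population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import BANDS, BASELINE_S, CHANNELS, FS, MAX_ANALYZED_HZ
from .recording import EEGRecording
from .selection import encode_score

LABELS = ("low", "moderate", "high")

#: RMS amplitude (microvolts) of the broadband 1/f background per channel.
BACKGROUND_RMS_UV = 10.0

#: Baseline RMS amplitude (microvolts) of each band-limited oscillation.
BAND_RMS_UV = {"theta": 6.0, "alpha": 8.0, "beta": 4.0, "gamma": 2.0}

#: Within-class standard deviation of the per-subject multiplicative
#: band-amplitude jitter (relative units).
BAND_JITTER_SD = 0.08

#: Log-sd of the per-subject global amplitude factor (skull/hair/contact
#: differences); cancelled by dB baseline normalization, not by raw power.
GLOBAL_GAIN_LOG_SD = 0.2

#: Soft-clip level in units of channel standard deviation. With a tanh
#: compressor at 2 sigma the artifact-free signal stays strictly below
#: 3x its own mean absolute amplitude, so only injected spikes trip the
#: outlier rule.
CLIP_SIGMA = 2.0

# class-conditional Beta shapes for balanced score generation, per level
_BALANCED_SHAPES = {"low": (2.0, 2.0), "moderate": (2.0, 2.0), "high": (2.0, 2.0)}
_LABEL_RANGES = {"low": (0.0, 200.0), "moderate": (200.0, 400.0), "high": (400.0, 800.0)}

# shape parameters of the bounded skewed score families (scaled Beta on 0-800)
_SKEW_SHAPES = {"positive": (2.0, 5.0), "negative": (5.0, 2.0)}


@dataclass
class CohortConfig:
    """Generation parameters for a synthetic cohort.

    ``effect_size`` scales the planted between-class band-power shift in
    units such that 1.0 separates adjacent class means by several within-class
    standard deviations of the band amplitude (see :class:`ClassSignature`);
    0.0 removes all label dependence. ``artifact_rate`` is expected spikes
    per channel per minute. ``dc_offset`` is the constant acquisition
    displacement in microvolts added to every channel.
    """

    n_subjects: int = 90
    duration_s: float = 60.0
    baseline_s: float = BASELINE_S
    fs: float = FS
    n_channels: int = len(CHANNELS)
    effect_size: float = 1.0
    artifact_rate: float = 2.0
    dc_offset: float = 200.0
    seed: int = 0
    score_mode: str = "balanced"  # or "empirical" (skewed families + thresholds)
    band_rms: dict | None = None  # per-band oscillation RMS override (uV); {} = pure background

    def __post_init__(self):
        if self.n_subjects < 3:
            raise ValueError("need at least one subject per class level")
        if self.baseline_s < 30:
            raise ValueError("baseline must be at least 30 s")
        if self.fs <= 2 * MAX_ANALYZED_HZ:
            raise ValueError(
                f"fs={self.fs} violates Nyquist for content up to {MAX_ANALYZED_HZ} Hz"
            )
        if self.n_channels < 1 or self.n_channels > len(CHANNELS):
            raise ValueError(f"n_channels must be in [1, {len(CHANNELS)}]")
        if self.effect_size < 0 or self.artifact_rate < 0:
            raise ValueError("effect_size and artifact_rate must be non-negative")
        if self.score_mode not in ("balanced", "empirical"):
            raise ValueError(f"unknown score_mode {self.score_mode!r}")
        min_s = 256 / self.fs
        if self.duration_s < min_s:
            raise ValueError(
                f"duration_s={self.duration_s} shorter than one STFT window; "
                f"minimum is {min_s:g} s at fs={self.fs}"
            )

    @property
    def channel_labels(self) -> tuple:
        return CHANNELS[: self.n_channels]


@dataclass
class ClassSignature:
    """Per-class, per-band fractional amplitude shifts planted in the task.

    ``band_shifts[label][band]`` is the fractional change of that band's
    oscillation RMS amplitude at ``effect_size = 1``; the realized amplitude
    multiplier is ``1 + effect_size * shift`` (floored at 0.05). Baseline
    segments always use multiplier 1, so dB-normalized features isolate the
    planted effect.
    """

    band_shifts: dict = field(
        default_factory=lambda: {
            "low": {"theta": -0.35},
            "moderate": {"theta": 0.0},
            "high": {"theta": 0.35},
        }
    )

    def __post_init__(self):
        for label, shifts in self.band_shifts.items():
            if label not in LABELS:
                raise ValueError(f"unknown class label {label!r}")
            for band, s in shifts.items():
                if band not in BANDS:
                    raise ValueError(f"unknown band {band!r}")
                if 1 + s < 0:
                    raise ValueError("shift would make band power negative")

    def multiplier(self, label: str, band: str, effect_size: float) -> float:
        shift = self.band_shifts.get(label, {}).get(band, 0.0)
        return max(1.0 + effect_size * shift, 0.05)

    def separation_ok(self, effect_size: float, within_sd: float = BAND_JITTER_SD) -> bool:
        """Do all class pairs differ by >= effect_size * within_sd in some band?"""
        if effect_size == 0:
            return True
        for a in LABELS:
            for b in LABELS:
                if a >= b:
                    continue
                gap = max(
                    abs(self.multiplier(a, band, effect_size) - self.multiplier(b, band, effect_size))
                    for band in BANDS
                )
                if gap < effect_size * within_sd:
                    return False
        return True


def default_signatures() -> dict:
    """Planted signatures per skill: attention in theta, memory in alpha."""
    return {
        "fa": ClassSignature(),
        "wm": ClassSignature(
            band_shifts={
                "low": {"alpha": -0.35},
                "moderate": {"alpha": 0.0},
                "high": {"alpha": 0.35},
            }
        ),
    }


def generate_scores(n: int, skew: str, seed: int) -> np.ndarray:
    """Draw ``n`` cognitive scores on [0, 800] from a bounded skewed family.

    ``skew='positive'`` uses 800*Beta(2, 5) (long right tail, as observed for
    focused attention); ``skew='negative'`` uses 800*Beta(5, 2) (long left
    tail, as for working memory). The sign of the sample skewness is forced
    by construction for all but tiny ``n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    try:
        a, b = _SKEW_SHAPES[skew]
    except KeyError:
        raise ValueError(f"skew must be 'positive' or 'negative', got {skew!r}") from None
    rng = np.random.default_rng(seed)
    return 800.0 * rng.beta(a, b, size=n)


def _synth_band_noise(rng, n, fs, low, high, unit_rms=True):
    """Band-limited Gaussian noise via random-phase spectral synthesis."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros_like(freqs)
    sel = (freqs >= low) & (freqs < high)
    amp[sel] = 1.0
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    spec = amp * np.exp(1j * phases)
    x = np.fft.irfft(spec, n=n)
    if unit_rms:
        rms = np.sqrt(np.mean(x**2))
        if rms > 0:
            x /= rms
    return x


def _synth_pink(rng, n, fs, f_min=1.0, f_max=MAX_ANALYZED_HZ):
    """1/f-power background, band-limited to [0.5, f_max) Hz, unit RMS."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros_like(freqs)
    sel = (freqs >= 0.5) & (freqs < f_max)
    # amplitude ~ 1/sqrt(f) => power ~ 1/f; flatten below f_min to bound drift
    amp[sel] = 1.0 / np.sqrt(np.maximum(freqs[sel], f_min))
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    x = np.fft.irfft(amp * np.exp(1j * phases), n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _generate_channels(band_multipliers: dict, cfg: CohortConfig, rng) -> np.ndarray:
    """Assemble all channels: background + oscillations + clip + spikes + DC.

    ``band_multipliers`` maps band name -> task-segment amplitude multiplier.
    The baseline segment always uses multiplier 1. The label enters only
    through these scalars, so identical seeds with effect_size = 0 yield
    identical recordings regardless of label.
    """
    n_base = int(round(cfg.baseline_s * cfg.fs))
    n_task = int(round(cfg.duration_s * cfg.fs))
    n = n_base + n_task
    gain = float(np.exp(rng.normal(0.0, GLOBAL_GAIN_LOG_SD)))
    band_rms = BAND_RMS_UV if cfg.band_rms is None else cfg.band_rms
    data = np.empty((cfg.n_channels, n))
    for ch in range(cfg.n_channels):
        x = BACKGROUND_RMS_UV * _synth_pink(rng, n, cfg.fs)
        for band, (low, high) in BANDS.items():
            osc = _synth_band_noise(rng, n, cfg.fs, low, min(high, MAX_ANALYZED_HZ))
            jitter = max(1.0 + rng.normal(0.0, BAND_JITTER_SD), 0.05)
            base_amp = band_rms.get(band, 0.0) * jitter
            mult = band_multipliers.get(band, 1.0)
            x[:n_base] += base_amp * osc[:n_base]
            x[n_base:] += base_amp * mult * osc[n_base:]
        x *= gain
        # tanh soft clip keeps the artifact-free signal below 3x mean |x|
        c = CLIP_SIGMA * np.std(x)
        if c > 0:
            x = c * np.tanh(x / c)
        # Poisson spike artifacts, amplitude 4-8x background RMS, width 1-3
        n_spikes = rng.poisson(cfg.artifact_rate * (n / cfg.fs) / 60.0)
        rms = np.sqrt(np.mean(x**2))
        for _ in range(n_spikes):
            pos = int(rng.integers(0, n))
            width = int(rng.integers(1, 4))
            amp = rng.uniform(4.0, 8.0) * rms * rng.choice([-1.0, 1.0])
            x[pos : pos + width] = amp
        data[ch] = x + cfg.dc_offset
    return data


def generate_recording(
    label: str, cfg: CohortConfig, signature: ClassSignature | None = None, seed: int = 0
) -> EEGRecording:
    """Generate one recording whose task segment carries ``label``'s signature."""
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    signature = signature if signature is not None else ClassSignature()
    mult = {band: signature.multiplier(label, band, cfg.effect_size) for band in BANDS}
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    data = _generate_channels(mult, cfg, rng)
    n_base = int(round(cfg.baseline_s * cfg.fs))
    return EEGRecording(
        data=data,
        fs=cfg.fs,
        channel_labels=cfg.channel_labels,
        baseline_span=(0, n_base),
        subject_id=f"sim{seed:06d}",
    )


@dataclass
class ScoreRecord:
    """Per-subject cognitive scores (0-800) and their three-level encodings."""

    subject_id: str
    fa_score: float
    wm_score: float

    @property
    def fa_label(self) -> str:
        return encode_score(self.fa_score)

    @property
    def wm_label(self) -> str:
        return encode_score(self.wm_score)


def _balanced_labels(n, rng):
    labels = np.array([LABELS[i % 3] for i in range(n)], dtype=object)
    return labels[rng.permutation(n)]


def _score_for_label(label, rng):
    lo, hi = _LABEL_RANGES[label]
    a, b = _BALANCED_SHAPES[label]
    s = lo + (hi - lo) * rng.beta(a, b)
    # keep strictly inside the half-open class interval
    return float(np.clip(s, lo, np.nextafter(hi, lo)))


def generate_cohort(cfg: CohortConfig, signatures: dict | None = None):
    """Generate one recording and one :class:`ScoreRecord` per subject.

    ``signatures`` maps skill name ('fa', 'wm') to a :class:`ClassSignature`;
    each subject's recording carries the product of the multipliers of their
    per-skill labels, so both effects coexist in distinct bands. In
    ``balanced`` score mode labels are assigned round-robin and shuffled per
    skill; in ``empirical`` mode scores are drawn from the skewed families
    (FA positive, WM negative) and labels follow from the 200/400 thresholds.

    Returns ``(recordings, score_records)``, reproducible bit-for-bit from
    ``cfg.seed``.
    """
    signatures = signatures if signatures is not None else default_signatures()
    root = np.random.SeedSequence(cfg.seed)
    ss_labels, ss_subjects = root.spawn(2)
    rng = np.random.default_rng(ss_labels)
    n = cfg.n_subjects

    if cfg.score_mode == "balanced":
        fa_labels = _balanced_labels(n, rng)
        wm_labels = _balanced_labels(n, rng)
        fa_scores = np.array([_score_for_label(l, rng) for l in fa_labels])
        wm_scores = np.array([_score_for_label(l, rng) for l in wm_labels])
    else:
        fa_scores = 800.0 * rng.beta(*_SKEW_SHAPES["positive"], size=n)
        wm_scores = 800.0 * rng.beta(*_SKEW_SHAPES["negative"], size=n)
        fa_labels = np.array([encode_score(s) for s in fa_scores], dtype=object)
        wm_labels = np.array([encode_score(s) for s in wm_scores], dtype=object)

    recordings, records = [], []
    subject_seeds = ss_subjects.spawn(n)
    for i in range(n):
        mult = {}
        for band in BANDS:
            m = 1.0
            for skill, label in (("fa", fa_labels[i]), ("wm", wm_labels[i])):
                sig = signatures.get(skill)
                if sig is not None:
                    m *= sig.multiplier(label, band, cfg.effect_size)
            mult[band] = m
        sid = f"S{i:03d}"
        srng = np.random.default_rng(subject_seeds[i])
        data = _generate_channels(mult, cfg, srng)
        n_base = int(round(cfg.baseline_s * cfg.fs))
        recordings.append(
            EEGRecording(
                data=data,
                fs=cfg.fs,
                channel_labels=cfg.channel_labels,
                baseline_span=(0, n_base),
                subject_id=sid,
            )
        )
        records.append(ScoreRecord(sid, float(fa_scores[i]), float(wm_scores[i])))
    return recordings, records
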