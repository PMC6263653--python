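"""File formats: delimited recordings/scores/features, EDF reading.

The delimited recording dialect is fixed for bit-exact round-trips:
comma-separated, UTF-8, '.' decimal, a header row of channel labels with a
leading sample-index column, and ``# key=value`` comment lines carrying the
sampling rate, baseline span and subject id. Floats are written with 17
significant digits, which round-trips IEEE doubles exactly.

EDF (European Data Format) recordings are read through ``mne`` when it is
installed; recordings are always written in the delimited dialect (no EDF
export backend is required of the environment).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import CHANNELS
from .recording import EEGRecording

_FLOAT_FMT = "%.17g"


def write_recording(rec: EEGRecording, path) -> Path:
    """Write a recording in the delimited dialect."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# fs={rec.fs!r}\n")
        fh.write(f"# baseline_span={rec.baseline_span[0]},{rec.baseline_span[1]}\n")
        fh.write(f"# subject_id={rec.subject_id}\n")
        fh.write("index," + ",".join(rec.channel_labels) + "\n")
        idx = np.arange(rec.n_samples)[:, None]
        np.savetxt(
            fh,
            np.column_stack([idx, rec.data.T]),
            fmt=["%d"] + [_FLOAT_FMT] * rec.n_channels,
            delimiter=",",
        )
    return path


def read_recording(path, expect_fs: float | None = None, expect_channels=None) -> EEGRecording:
    """Read a recording written by :func:`write_recording` or an EDF file.

    ``expect_fs`` / ``expect_channels`` enforce the pipeline configuration:
    a sampling-rate mismatch is an error (no silent resampling), and unknown
    channel labels are named in the error.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        rec = _read_edf(path)
    else:
        rec = _read_delimited(path)
    if expect_fs is not None and rec.fs != expect_fs:
        raise ValueError(
            f"{path.name}: sampling rate {rec.fs} Hz does not match the "
            f"configured {expect_fs} Hz (resampling is not performed)"
        )
    if expect_channels is not None:
        expected = tuple(expect_channels)
        if tuple(rec.channel_labels) != expected:
            unknown = [c for c in rec.channel_labels if c not in expected]
            raise ValueError(
                f"{path.name}: channel labels do not match the montage; "
                f"unexpected: {unknown or rec.channel_labels}"
            )
    return rec


def _read_delimited(path: Path) -> EEGRecording:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, float_precision="round_trip")
    if df.columns[0] != "index":
        raise ValueError(f"{path.name}: first column must be the sample index")
    labels = tuple(df.columns[1:])
    span = (0, 0)
    if "baseline_span" in meta:
        a, _, b = meta["baseline_span"].partition(",")
        span = (int(a), int(b))
    return EEGRecording(
        data=df.iloc[:, 1:].to_numpy(dtype=float).T,
        fs=float(meta.get("fs", 128.0)),
        channel_labels=labels,
        baseline_span=span,
        subject_id=meta.get("subject_id", path.stem),
    )


def _read_edf(path: Path) -> EEGRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("reading EDF requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = tuple(raw.ch_names)
    unknown = [c for c in labels if c not in CHANNELS]
    if unknown:
        raise ValueError(f"{path.name}: unexpected channel labels {unknown}")
    return EEGRecording(
        data=raw.get_data() * 1e6,  # mne returns volts
        fs=float(raw.info["sfreq"]),
        channel_labels=labels,
        subject_id=path.stem,
    )


def write_scores(records, path) -> Path:
    """Write score records as subject_id, FA, WM columns."""
    df = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "FA": [r.fa_score for r in records],
            "WM": [r.wm_score for r in records],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return Path(path)


def read_scores(path) -> pd.DataFrame:
    """Read a score table; requires subject_id, FA and WM columns."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"subject_id", "FA", "WM"} - set(df.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    bad = df[(df.FA < 0) | (df.FA > 800) | (df.WM < 0) | (df.WM > 800)]
    if len(bad):
        raise ValueError(f"scores outside 0-800 for subjects: {list(bad.subject_id)}")
    return df.set_index("subject_id")


def write_features(table: pd.DataFrame, path) -> Path:
    """Write a subjects x features table (index = subject_id)."""
    table.to_csv(path, index=True, index_label="subject_id", float_format=_FLOAT_FMT)
    return Path(path)


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id", float_precision="round_trip")


def write_json(obj, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path
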