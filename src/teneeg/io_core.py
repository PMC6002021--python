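"""Epoch containers, ratings tables, preprocessing, configuration and logging.

EEG trials are held as an :class:`EpochSet`: one subject's ordered list of
``channels x samples`` arrays (trials may differ in length -- the listening
stimuli last 13-22 s), a 10/20-system channel-label list and a sampling rate.

On disk an epoch set is a directory containing ``epochs.json`` (subject id,
channel labels, sampling rate, trial manifest) plus one raw little-endian
float64 binary per trial, row-major channels x samples.  The format is
lossless, language-neutral and ragged-trial friendly.  EDF files can also be
read (via :mod:`mne`, if installed); the native container is the canonical
pipeline format.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger("teneeg")

# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class TeneegError(Exception):
    """Base class for errors raised by this package."""


class FormatError(TeneegError):
    """An on-disk container or table violates the expected format."""


class RatingRangeError(TeneegError):
    """A rating value lies outside its printed scale bounds."""


class ParameterError(TeneegError, ValueError):
    """An operation was called with invalid parameters."""


class ShapeMismatchError(TeneegError):
    """Array dimensions do not match what a fitted model expects."""


class DegenerateDataError(TeneegError):
    """Input data carry no usable variation (constant column, empty band...)."""


class MontageError(TeneegError):
    """A channel label has no coordinates in the montage."""


# ---------------------------------------------------------------------------
# Logging / configuration
# ---------------------------------------------------------------------------


def setup_logging(level: str = "INFO") -> None:
    """Configure the package logger for CLI use."""
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def load_config(path: str | Path) -> dict:
    """Load a JSON or YAML configuration file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yml", ".yaml"}:
        import yaml

        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise FormatError(f"config file {path} must contain a mapping")
    return cfg


# ---------------------------------------------------------------------------
# EpochSet
# ---------------------------------------------------------------------------


@dataclass
class EpochSet:
    """One subject's EEG trials.

    Parameters
    ----------
    subject_id
        Identifier used to join against the ratings table.
    trials
        Ordered list of ``(M, T_n)`` float arrays; ``T_n`` may differ per
        trial but every trial has the same ``M`` channels, in
        ``channel_labels`` order.
    channel_labels
        10/20-system names, length ``M``.
    sampling_rate
        Sampling rate in Hz, shared by all trials.
    """

    subject_id: str
    trials: list[np.ndarray]
    channel_labels: list[str]
    sampling_rate: float

    def __post_init__(self) -> None:
        self.trials = [np.asarray(t, dtype=np.float64) for t in self.trials]
        self.channel_labels = list(self.channel_labels)
        self.sampling_rate = float(self.sampling_rate)
        self.validate()

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise FormatError("sampling_rate must be positive")
        m = len(self.channel_labels)
        if m == 0:
            raise FormatError("channel_labels is empty")
        if len(set(self.channel_labels)) != m:
            raise FormatError("channel_labels contains duplicates")
        for n, trial in enumerate(self.trials):
            if trial.ndim != 2 or trial.shape[0] != m:
                raise FormatError(
                    f"trial {n}: expected {m} channel rows, got shape {trial.shape}"
                )
            if trial.shape[1] < 2:
                raise FormatError(f"trial {n}: needs at least 2 samples")
            if not np.all(np.isfinite(trial)):
                raise FormatError(f"trial {n}: contains non-finite samples")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)


_META_NAME = "epochs.json"


def write_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Write an :class:`EpochSet` to a container directory (lossless)."""
    epochs.validate()
    if epochs.n_trials == 0:
        raise FormatError("refusing to write an epoch set with no trials")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = []
    for n, trial in enumerate(epochs.trials):
        fname = f"trial_{n:04d}.f64"
        arr = np.ascontiguousarray(trial, dtype="<f8")
        (path / fname).write_bytes(arr.tobytes())
        manifest.append({"file": fname, "n_samples": int(trial.shape[1])})
    meta = {
        "subject_id": epochs.subject_id,
        "channel_labels": epochs.channel_labels,
        "sampling_rate": epochs.sampling_rate,
        "trials": manifest,
    }
    (path / _META_NAME).write_text(json.dumps(meta, indent=1))


def read_epochs(path: str | Path) -> EpochSet:
    """Read an epoch container directory (or an EDF file) into an EpochSet.

    EDF reading requires :mod:`mne` and returns the whole recording as a
    single trial; the native container is the format the pipeline round-trips.
    """
    path = Path(path)
    if path.is_file() and path.suffix.lower() == ".edf":
        return _read_edf(path)
    meta_path = path / _META_NAME
    if not meta_path.is_file():
        raise FormatError(f"{path} is not an epoch container ({_META_NAME} missing)")
    try:
        meta = json.loads(meta_path.read_text())
        labels = list(meta["channel_labels"])
        rate = float(meta["sampling_rate"])
        subject = str(meta["subject_id"])
        manifest = meta["trials"]
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{meta_path}: missing or malformed metadata: {exc}") from exc
    m = len(labels)
    trials = []
    for n, entry in enumerate(manifest):
        fpath = path / entry["file"]
        t = int(entry["n_samples"])
        raw = np.frombuffer(fpath.read_bytes(), dtype="<f8")
        if raw.size != m * t:
            raise FormatError(
                f"trial {n} ({fpath.name}): {raw.size} values on disk do not "
                f"match {m} channels x {t} samples declared in metadata"
            )
        trials.append(raw.reshape(m, t).copy())
    return EpochSet(subject, trials, labels, rate)


def _read_edf(path: Path) -> EpochSet:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise FormatError("reading EDF files requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()
    return EpochSet(path.stem, [data], list(raw.ch_names), float(raw.info["sfreq"]))


# ---------------------------------------------------------------------------
# RatingsTable
# ---------------------------------------------------------------------------

RATING_COLUMNS = ("subject", "trial", "MOS", "VAL", "ARL")
RATING_BOUNDS = {"MOS": (1.0, 5.0), "VAL": (1.0, 9.0), "ARL": (1.0, 9.0)}
SCALES = ("MOS", "VAL", "ARL")


@dataclass
class RatingsTable:
    """Per-trial subjective ratings: MOS on 1-5, valence/arousal on 1-9."""

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.frame
        if list(df.columns) != list(RATING_COLUMNS):
            raise FormatError(
                f"ratings table needs columns {','.join(RATING_COLUMNS)}, "
                f"got {','.join(map(str, df.columns))}"
            )
        dup = df.duplicated(subset=["subject", "trial"])
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            raise FormatError(f"duplicate (subject, trial) key at row {row + 1}")
        for col, (lo, hi) in RATING_BOUNDS.items():
            vals = df[col].to_numpy(dtype=float)
            bad = ~((vals >= lo) & (vals <= hi))
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise RatingRangeError(
                    f"row {row + 1}: {col}={vals[row]} outside [{lo:g}, {hi:g}]"
                )

    def for_subject(self, subject_id: str) -> np.ndarray:
        """Response matrix (N x 3: MOS, VAL, ARL) in trial order."""
        sub = self.frame[self.frame["subject"] == subject_id]
        if sub.empty:
            raise FormatError(f"no ratings for subject {subject_id!r}")
        sub = sub.sort_values("trial")
        return sub[list(SCALES)].to_numpy(dtype=float)

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.frame["subject"]))


def read_ratings(path: str | Path) -> RatingsTable:
    """Read a ratings CSV with header exactly ``subject,trial,MOS,VAL,ARL``."""
    df = pd.read_csv(path)
    return RatingsTable(df)


def write_ratings(table: RatingsTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def preprocess(
    epochs: EpochSet,
    low_hz: float = 0.5,
    high_hz: float = 50.0,
    target_rate: float | None = 256.0,
    order: int = 8,
) -> EpochSet:
    """Band-pass filter and decimate an epoch set.

    A zero-phase (forward-backward) Butterworth band-pass is applied at the
    original rate, then the signal is decimated to ``target_rate`` by an
    integer factor with anti-alias filtering.  Zero-phase filtering matters
    here because downstream phase-difference features would be corrupted by a
    causal filter's phase distortion.  The default ``order`` of 8 makes the
    zero-phase response steep enough to suppress a 60 Hz mains tone by more
    than 20 dB with the standard 0.5-50 Hz band.  Defaults reproduce the
    usual EEG recipe (0.5-50 Hz, 512 -> 256 Hz).
    """
    fs = epochs.sampling_rate
    if not (0 < low_hz < high_hz < fs / 2):
        raise ParameterError(
            f"band edges must satisfy 0 < low < high < rate/2, got "
            f"({low_hz}, {high_hz}) at {fs} Hz"
        )
    if target_rate is None:
        target_rate = fs
    q, rem = divmod(fs, target_rate)
    if rem != 0 or target_rate <= 0:
        raise ParameterError(
            f"target_rate {target_rate} must divide the sampling rate {fs}"
        )
    q = int(q)
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    out = []
    for trial in epochs.trials:
        filtered = signal.sosfiltfilt(sos, trial, axis=-1)
        if q > 1:
            filtered = signal.decimate(filtered, q, axis=-1, zero_phase=True)
        out.append(np.ascontiguousarray(filtered))
    return EpochSet(epochs.subject_id, out, list(epochs.channel_labels), target_rate)
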