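"""Core in-memory containers for sensor streams, analysis windows and labels.

All heavy numerics live elsewhere; these are validated dataclasses plus a
thin pandas-backed label table. Units are fixed package-wide: time in
seconds, RR intervals in milliseconds, accelerometer axes in g.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingValueError, ParameterError, VocabularyError

#: Closed vocabulary of per-window rhythm designations.
LABELS = ("AF", "PAC_PVC", "NSR", "NOISE")

LABEL_COLUMNS = ("subject_id", "window_index", "window_start", "label")


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ParameterError(f"{name} must be one-dimensional")
    if arr.size == 0:
        raise ParameterError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise MissingValueError(f"{name} contains NaN/inf values")
    return arr


@dataclass
class PpgRecord:
    """A single-channel PPG stream with explicit sampling metadata.

    The smartwatch photoplethysmogram is in arbitrary optical units; only
    its sampling rate and start time carry physical meaning.
    """

    subject_id: str
    sampling_rate: float  # Hz
    start_time: float  # seconds (epoch or relative)
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")
        self.samples = _as_float_array(self.samples, "samples")

    @property
    def duration(self) -> float:
        """Record span in seconds (n / fs)."""
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate


@dataclass
class AccelRecord:
    """Tri-axial accelerometer stream time-aligned with a PPG record."""

    subject_id: str
    sampling_rate: float  # Hz
    start_time: float  # seconds
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    unit: str = "g"

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")
        self.x = _as_float_array(self.x, "x")
        self.y = _as_float_array(self.y, "y")
        self.z = _as_float_array(self.z, "z")
        if not (self.x.size == self.y.size == self.z.size):
            raise ParameterError("accelerometer axes must have equal length")

    @property
    def duration(self) -> float:
        return self.x.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.x.size) / self.sampling_rate

    def xyz(self) -> np.ndarray:
        """Axes stacked as an (n, 3) array."""
        return np.column_stack([self.x, self.y, self.z])


@dataclass
class Segment:
    """One 30-second analysis window pairing a PPG slice with its
    wall-clock-matched accelerometer slice (kept at native rate)."""

    window_index: int
    window_start: float  # seconds
    window_length: float  # seconds
    ppg_slice: np.ndarray
    accel_slice: np.ndarray  # (n, 3), may be empty if no accel coverage
    ppg_rate: float
    accel_rate: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.window_index < 0:
            raise ParameterError("window_index must be non-negative")
        if self.window_length <= 0:
            raise ParameterError("window_length must be positive")
        self.ppg_slice = np.asarray(self.ppg_slice, dtype=float)
        self.accel_slice = np.asarray(self.accel_slice, dtype=float)
        if self.accel_slice.size and self.accel_slice.ndim != 2:
            raise ParameterError("accel_slice must be (n, 3)")


@dataclass
class RrSeries:
    """Beat times (s, within segment) and inter-beat RR intervals (ms).

    ``rr_intervals`` are the successive peak-time differences that survived
    the physiologic-bounds filter; ``n_removed`` records how many were
    discarded.
    """

    peak_times: np.ndarray  # seconds, strictly increasing
    rr_intervals: np.ndarray  # milliseconds
    n_removed: int = 0

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.rr_intervals = np.asarray(self.rr_intervals, dtype=float)
        if self.peak_times.size and np.any(np.diff(self.peak_times) <= 0):
            raise ParameterError("peak_times must be strictly increasing")
        if np.any(self.rr_intervals <= 0):
            raise ParameterError("rr_intervals must be positive")

    @property
    def mean_rr(self) -> float:
        """Mean RR interval in milliseconds."""
        return float(np.mean(self.rr_intervals))

    def __len__(self) -> int:
        return int(self.rr_intervals.size)


def validate_label_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a label table against the closed vocabulary and key uniqueness.

    Returns the table with canonical column order and dtypes.
    """
    missing = [c for c in LABEL_COLUMNS if c not in table.columns]
    if missing:
        raise VocabularyError(f"label table missing columns: {missing}")
    table = table.loc[:, list(LABEL_COLUMNS)].copy()
    bad = set(table["label"].unique()) - set(LABELS)
    if bad:
        raise VocabularyError(f"unknown rhythm labels: {sorted(bad)}")
    if table.duplicated(subset=["subject_id", "window_index"]).any():
        raise VocabularyError("duplicate (subject_id, window_index) keys")
    table["window_index"] = table["window_index"].astype(int)
    table["window_start"] = table["window_start"].astype(float)
    table["subject_id"] = table["subject_id"].astype(str)
    table["label"] = table["label"].astype(str)
    return table


def make_label_table(rows) -> pd.DataFrame:
    """Build a validated label table from an iterable of
    (subject_id, window_index, window_start, label) tuples."""
    df = pd.DataFrame(list(rows), columns=list(LABEL_COLUMNS))
    return validate_label_table(df)
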