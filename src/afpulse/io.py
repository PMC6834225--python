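"""CSV readers/writers for sensor streams and label tables, and the
30-second windowing that every downstream stage consumes.

File contracts (comma-separated, '.' decimal, UTF-8, header required):

* PPG:    ``timestamp,ppg``
* Accel:  ``timestamp,ax,ay,az``
* Labels: ``subject_id,window_index,window_start,label``

Timestamps are seconds and must be strictly increasing at a constant rate;
the caller always declares the sampling rate explicitly (the watch hardware
rates are deployment metadata, never assumed).
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    MissingValueError,
    MonotonicityError,
    ParameterError,
)
from .records import (
    AccelRecord,
    LABEL_COLUMNS,
    PpgRecord,
    Segment,
    validate_label_table,
)

logger = logging.getLogger(__name__)

#: Default analysis window length in seconds.
WINDOW_LENGTH = 30.0


def _read_csv(path, columns) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        # round_trip: exact IEEE parsing so write -> read is lossless
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise FormatError(f"{path}: empty stream")
    df = df.loc[:, list(columns)]
    if df.isna().any().any():
        raise MissingValueError(f"{path}: stream contains missing values")
    return df


def _check_monotone(ts: np.ndarray, path) -> None:
    if np.any(np.diff(ts) <= 0):
        raise MonotonicityError(f"{path}: timestamps not strictly increasing")


def read_ppg(path, sampling_rate: float, subject_id: str = "") -> PpgRecord:
    """Load a ``timestamp,ppg`` CSV into a validated :class:`PpgRecord`.

    Raises ``FileNotFoundError``, :class:`MonotonicityError`,
    :class:`MissingValueError` or :class:`FormatError` on the
    corresponding defect; never imputes.
    """
    df = _read_csv(path, ("timestamp", "ppg"))
    ts = df["timestamp"].to_numpy(dtype=float)
    _check_monotone(ts, path)
    return PpgRecord(
        subject_id=subject_id,
        sampling_rate=float(sampling_rate),
        start_time=float(ts[0]),
        samples=df["ppg"].to_numpy(dtype=float),
    )


def read_accel(path, sampling_rate: float, subject_id: str = "") -> AccelRecord:
    """Load a ``timestamp,ax,ay,az`` CSV into an :class:`AccelRecord`."""
    df = _read_csv(path, ("timestamp", "ax", "ay", "az"))
    ts = df["timestamp"].to_numpy(dtype=float)
    _check_monotone(ts, path)
    return AccelRecord(
        subject_id=subject_id,
        sampling_rate=float(sampling_rate),
        start_time=float(ts[0]),
        x=df["ax"].to_numpy(dtype=float),
        y=df["ay"].to_numpy(dtype=float),
        z=df["az"].to_numpy(dtype=float),
    )


def write_ppg(path, record: PpgRecord, fmt: str = "%.17g") -> None:
    """Write a PPG record as ``timestamp,ppg`` (round-trips bit-exactly
    through :func:`read_ppg` for values representable at the format)."""
    df = pd.DataFrame({"timestamp": record.times, "ppg": record.samples})
    df.to_csv(path, index=False, float_format=fmt)


def write_accel(path, record: AccelRecord, fmt: str = "%.17g") -> None:
    df = pd.DataFrame(
        {"timestamp": record.times, "ax": record.x, "ay": record.y, "az": record.z}
    )
    df.to_csv(path, index=False, float_format=fmt)


def segment(
    ppg: PpgRecord,
    accel: AccelRecord | None = None,
    window_length: float = WINDOW_LENGTH,
) -> list[Segment]:
    """Cut time-aligned PPG/accelerometer records into half-open
    ``[t, t + window_length)`` windows over their overlapping span.

    Only complete windows are emitted (trailing partials are dropped), so
    the count is ``floor(overlap / window_length)``. The accelerometer
    slice is cropped to the same wall-clock interval at its native rate —
    no interpolation onto the PPG grid. Returns an empty list (with a
    warning logged) when the streams do not overlap.
    """
    if window_length <= 0:
        raise ParameterError("window_length must be positive")
    t0 = ppg.start_time
    t1 = ppg.start_time + ppg.duration
    if accel is not None:
        t0 = max(t0, accel.start_time)
        t1 = min(t1, accel.start_time + accel.duration)
    if t1 - t0 < window_length:
        logger.warning(
            "streams overlap for %.1f s < window length %.1f s; no segments",
            max(t1 - t0, 0.0),
            window_length,
        )
        return []

    n_windows = math.floor((t1 - t0) / window_length + 1e-9)
    n_ppg = int(round(window_length * ppg.sampling_rate))
    segments: list[Segment] = []
    for k in range(n_windows):
        start = t0 + k * window_length
        i0 = int(round((start - ppg.start_time) * ppg.sampling_rate))
        ppg_slice = ppg.samples[i0 : i0 + n_ppg]
        if ppg_slice.size < n_ppg:
            break  # numerical tail guard; partial windows are never emitted
        if accel is not None:
            j0 = int(math.ceil((start - accel.start_time) * accel.sampling_rate - 1e-9))
            j1 = int(
                math.ceil(
                    (start + window_length - accel.start_time) * accel.sampling_rate
                    - 1e-9
                )
            )
            accel_slice = accel.xyz()[j0:j1]
        else:
            accel_slice = np.empty((0, 3))
        segments.append(
            Segment(
                window_index=k,
                window_start=start,
                window_length=window_length,
                ppg_slice=ppg_slice,
                accel_slice=accel_slice,
                ppg_rate=ppg.sampling_rate,
                accel_rate=accel.sampling_rate if accel is not None else 0.0,
                subject_id=ppg.subject_id,
            )
        )
    return segments


def read_labels(path) -> pd.DataFrame:
    """Read a label CSV, enforcing the closed {AF, PAC_PVC, NSR, NOISE}
    vocabulary and (subject_id, window_index) uniqueness."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path, dtype={"subject_id": str}, keep_default_na=False, na_values=[]
    )
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return validate_label_table(df)


def write_labels(path, table: pd.DataFrame) -> None:
    """Write a validated label table; an empty table yields a header-only
    file and ``read_labels`` is the exact inverse."""
    table = validate_label_table(table)
    table.to_csv(path, index=False)
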