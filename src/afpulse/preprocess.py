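"""PPG conditioning and pulse-peak extraction for one 30-second window.

The chain is: zero-phase band-pass (0.5-5 Hz, covering heart-rate
fundamentals from 30 to 220 bpm plus low harmonics) -> local-maximum peak
picking with an adaptive amplitude threshold and a 300 ms refractory
period -> RR intervals in milliseconds with physiologic-bounds QC
([300, 2000] ms by default, i.e. 30-200 bpm).

Peak positions are refined to sub-sample precision by parabolic
interpolation of the three samples around each local maximum, so RR
resolution is not limited to the sampling grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .errors import ParameterError, UnanalyzableSegmentError
from .records import RrSeries


@dataclass
class PreprocessConfig:
    """Tunable conditioning/QC parameters with physiologic defaults.

    band_low, band_high : Hz
        Pass band of the zero-phase Butterworth filter.
    filter_order : int
        Order of each (sos) cascade half; applied forward-backward.
    refractory : s
        Minimum peak-to-peak spacing (300 ms ~ 200 bpm ceiling).
    threshold_fraction : float
        Peak acceptance threshold as a fraction of the rolling
        amplitude envelope.
    envelope_window : s
        Length of the centered rolling window for the amplitude envelope.
    rr_bounds : (ms, ms)
        Intervals outside this range are removed (count logged on the
        returned series), not merged.
    """

    band_low: float = 0.5
    band_high: float = 5.0
    filter_order: int = 3
    refractory: float = 0.3
    threshold_fraction: float = 0.4
    envelope_window: float = 3.0
    rr_bounds: tuple[float, float] = (300.0, 2000.0)


def bandpass(
    ppg_slice,
    sampling_rate: float,
    low: float = 0.5,
    high: float = 5.0,
    order: int = 3,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass; same length as the input.

    DC and drift are removed entirely (the pass band excludes 0 Hz), so a
    constant input maps to (numerically) zero.
    """
    if not 0 < low < high < sampling_rate / 2:
        raise ParameterError(
            f"invalid band ({low}, {high}) Hz for fs={sampling_rate} Hz"
        )
    x = np.asarray(ppg_slice, dtype=float)
    sos = signal.butter(order, [low, high], btype="bandpass", fs=sampling_rate, output="sos")
    return signal.sosfiltfilt(sos, x)


def _rolling_envelope(x: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    """Centered rolling 90th percentile of |x| — a robust amplitude scale
    that tracks slow gain changes without chasing single spikes."""
    n = max(int(round(window_s * fs)) | 1, 3)  # odd, >= 3
    return ndimage.percentile_filter(np.abs(x), percentile=90, size=n, mode="nearest")


def detect_peaks(
    filtered,
    sampling_rate: float,
    config: PreprocessConfig | None = None,
) -> np.ndarray:
    """Locate systolic pulse peaks in a filtered PPG slice.

    Returns strictly increasing fractional sample indices (parabolic
    sub-sample refinement). Raises :class:`UnanalyzableSegmentError` when
    fewer than three peaks survive, which covers flat-line and
    near-degenerate inputs.
    """
    cfg = config or PreprocessConfig()
    x = np.asarray(filtered, dtype=float)
    if x.size < 3:
        raise UnanalyzableSegmentError("segment too short for peak detection")
    scale = float(np.max(np.abs(x))) if x.size else 0.0
    if scale <= 0 or np.ptp(x) < 1e-12 * max(scale, 1.0):
        raise UnanalyzableSegmentError("flat-line segment: no pulse activity")

    distance = max(int(round(cfg.refractory * sampling_rate)), 1)
    idx, _ = signal.find_peaks(x, distance=distance)
    if idx.size == 0:
        raise UnanalyzableSegmentError("no local maxima found")
    envelope = _rolling_envelope(x, sampling_rate, cfg.envelope_window)
    keep = x[idx] > cfg.threshold_fraction * envelope[idx]
    idx = idx[keep]
    if idx.size < 3:
        raise UnanalyzableSegmentError(
            f"only {idx.size} pulse peaks found; need >= 3"
        )

    # Parabolic refinement around each integer peak.
    refined = idx.astype(float)
    interior = (idx > 0) & (idx < x.size - 1)
    i = idx[interior]
    denom = x[i - 1] - 2.0 * x[i] + x[i + 1]
    ok = np.abs(denom) > 1e-30
    shift = np.zeros_like(denom)
    shift[ok] = 0.5 * (x[i - 1] - x[i + 1])[ok] / denom[ok]
    refined[interior] += np.clip(shift, -0.5, 0.5)
    return refined


def peaks_to_rr(
    peak_indices,
    sampling_rate: float,
    bounds: tuple[float, float] = (300.0, 2000.0),
) -> RrSeries:
    """Convert peak indices to an RR series in milliseconds with QC.

    Intervals outside ``bounds`` are removed (their count is recorded on
    ``RrSeries.n_removed``); fewer than two surviving intervals makes the
    window unanalyzable.
    """
    peaks = np.asarray(peak_indices, dtype=float)
    if peaks.size < 3:
        raise UnanalyzableSegmentError("need >= 3 peaks for an RR series")
    if np.any(np.diff(peaks) <= 0):
        raise ParameterError("peak indices must be strictly increasing")
    times = peaks / sampling_rate
    rr = np.diff(times) * 1000.0
    lo, hi = bounds
    mask = (rr >= lo) & (rr <= hi)
    n_removed = int(np.sum(~mask))
    rr = rr[mask]
    if rr.size < 2:
        raise UnanalyzableSegmentError(
            f"only {rr.size} RR intervals within bounds {bounds}"
        )
    return RrSeries(peak_times=times, rr_intervals=rr, n_removed=n_removed)


def extract_rr(
    ppg_slice,
    sampling_rate: float,
    config: PreprocessConfig | None = None,
) -> RrSeries:
    """Full conditioning chain for one window: filter -> peaks -> RR."""
    cfg = config or PreprocessConfig()
    filt = bandpass(
        ppg_slice, sampling_rate, cfg.band_low, cfg.band_high, cfg.filter_order
    )
    peaks = detect_peaks(filt, sampling_rate, cfg)
    return peaks_to_rr(peaks, sampling_rate, cfg.rr_bounds)
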