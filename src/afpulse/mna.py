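"""Motion-noise artifact (MNA) screening for 30-second PPG windows.

A clean wrist PPG window is nearly a stationary tone train: its
short-time spectrum keeps a stable dominant frequency inside the cardiac
band (0.5-3 Hz), low spectral entropy, and most power in-band. Motion
artifact destroys all three. Severity is the mean of three normalized
spectral features — dominant-frequency instability, mean spectral
entropy, and out-of-band power fraction — escalated to 1.0 outright when
the gravity-removed accelerometer RMS exceeds a motion gate: significant
wrist acceleration by itself marks the window unanalyzable.

Features are computed on per-frame *normalized* spectra, so severity is
invariant to PPG amplitude rescaling and deterministic for a given
window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator

from .errors import ParameterError
from .records import Segment

#: Default decision threshold on severity; calibrated on the synthetic
#: clean/corrupted corpora (see docs/methods.md).
SEVERITY_THRESHOLD = 0.6


@dataclass
class MnaParams:
    """STFT framing, feature normalization and gating parameters.

    frame : s — Hann STFT frame length (4 s resolves 0.25 Hz).
    overlap : fraction of frame overlap between consecutive frames.
    band : Hz — cardiac band for dominant-frequency / in-band power.
    dfi_scale : Hz — dominant-frequency instability mapping to [0, 1].
    accel_gate : g — gravity-removed RMS above which the window is
        rejected outright.
    threshold : severity above which the window is *not* clean
        (rejection is strict: severity > threshold).
    """

    frame: float = 4.0
    overlap: float = 0.5
    band: tuple[float, float] = (0.5, 3.0)
    dfi_scale: float = 0.5
    accel_gate: float = 0.1
    threshold: float = SEVERITY_THRESHOLD


@dataclass
class MnaResult:
    """Per-window artifact assessment."""

    severity: float
    spectral_features: dict
    accel_rms: float
    is_clean: bool


def time_frequency_features(
    ppg_slice, sampling_rate: float, params: MnaParams | None = None
) -> dict:
    """Short-time spectral features of one PPG window.

    Returns ``dominant_freq_instability`` (SD across frames of the
    dominant cardiac-band frequency, Hz), ``spectral_entropy`` (mean
    per-frame Shannon entropy of the normalized spectrum, scaled to
    [0, 1] by log of the bin count) and ``inband_fraction`` (mean
    per-frame fraction of non-DC power inside the cardiac band). A
    constant window maps to all-zero features by convention.
    """
    p = params or MnaParams()
    x = np.asarray(ppg_slice, dtype=float)
    if x.size / sampling_rate < 10.0:
        raise ParameterError("time-frequency features need >= 10 s of signal")
    if np.ptp(x) == 0:
        return {
            "dominant_freq_instability": 0.0,
            "spectral_entropy": 0.0,
            "inband_fraction": 0.0,
        }
    nperseg = int(round(p.frame * sampling_rate))
    noverlap = int(round(nperseg * p.overlap))
    freqs, _, sxx = signal.spectrogram(
        x - np.mean(x),
        fs=sampling_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        mode="psd",
    )
    # drop the DC bin; normalize each frame to a probability distribution
    freqs = freqs[1:]
    sxx = sxx[1:, :]
    power = sxx.sum(axis=0)
    power[power == 0] = 1.0
    pmat = sxx / power

    in_band = (freqs >= p.band[0]) & (freqs <= p.band[1])
    if not np.any(in_band):
        raise ParameterError("cardiac band contains no frequency bins")
    band_freqs = freqs[in_band]
    dom = band_freqs[np.argmax(sxx[in_band, :], axis=0)]
    dfi = float(np.std(dom))

    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.nansum(np.where(pmat > 0, pmat * np.log(pmat), 0.0), axis=0)
    ent_norm = float(np.mean(ent) / np.log(pmat.shape[0]))

    ibf = float(np.mean(pmat[in_band, :].sum(axis=0)))
    return {
        "dominant_freq_instability": dfi,
        "spectral_entropy": ent_norm,
        "inband_fraction": ibf,
    }


def accel_amplitude(accel_slice) -> float:
    """Gravity-removed RMS of the accelerometer vector magnitude.

    Per-axis means (gravity plus slow posture offsets) are subtracted
    before taking the vector magnitude, so a watch resting at any
    orientation scores 0.
    """
    a = np.asarray(accel_slice, dtype=float)
    if a.size == 0:
        return 0.0
    if a.ndim != 2 or a.shape[1] != 3:
        raise ParameterError("accel_slice must be (n, 3)")
    centered = a - a.mean(axis=0, keepdims=True)
    return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))


def classify_mna(
    features: dict, accel_rms: float, params: MnaParams | None = None
) -> MnaResult:
    """Combine spectral features and accelerometer amplitude into a
    severity score and the clean/rejected decision.

    severity = mean(clip(dfi/dfi_scale, 0, 1), spectral_entropy,
    1 - inband_fraction); forced to 1.0 when ``accel_rms`` exceeds the
    motion gate. A window is clean iff severity <= threshold.
    """
    p = params or MnaParams()
    vals = [
        features["dominant_freq_instability"],
        features["spectral_entropy"],
        features["inband_fraction"],
    ]
    if not np.all(np.isfinite(vals)) or not np.isfinite(accel_rms):
        raise ParameterError("MNA features must be finite")
    dfi_norm = min(max(features["dominant_freq_instability"] / p.dfi_scale, 0.0), 1.0)
    ent_norm = min(max(features["spectral_entropy"], 0.0), 1.0)
    oob = min(max(1.0 - features["inband_fraction"], 0.0), 1.0)
    severity = (dfi_norm + ent_norm + oob) / 3.0
    if accel_rms > p.accel_gate:
        severity = 1.0
    return MnaResult(
        severity=float(severity),
        spectral_features=dict(features),
        accel_rms=float(accel_rms),
        is_clean=bool(severity <= p.threshold),
    )


def assess_segment(seg: Segment, params: MnaParams | None = None) -> MnaResult:
    """MNA assessment of one :class:`Segment`."""
    p = params or MnaParams()
    feats = time_frequency_features(seg.ppg_slice, seg.ppg_rate, p)
    rms = accel_amplitude(seg.accel_slice)
    return classify_mna(feats, rms, p)


class MotionArtifactDetector(BaseEstimator):
    """sklearn-style wrapper: predicts per-segment clean (True) /
    rejected (False), with ``decision_function`` returning severity."""

    def __init__(
        self,
        frame: float = 4.0,
        overlap: float = 0.5,
        band: tuple[float, float] = (0.5, 3.0),
        dfi_scale: float = 0.5,
        accel_gate: float = 0.1,
        threshold: float = SEVERITY_THRESHOLD,
    ):
        self.frame = frame
        self.overlap = overlap
        self.band = band
        self.dfi_scale = dfi_scale
        self.accel_gate = accel_gate
        self.threshold = threshold

    def fit(self, X=None, y=None):
        self.params_ = MnaParams(
            frame=self.frame,
            overlap=self.overlap,
            band=tuple(self.band),
            dfi_scale=self.dfi_scale,
            accel_gate=self.accel_gate,
            threshold=self.threshold,
        )
        return self

    def assess(self, X) -> list[MnaResult]:
        if not hasattr(self, "params_"):
            self.fit()
        return [assess_segment(seg, self.params_) for seg in X]

    def predict(self, X) -> np.ndarray:
        return np.array([r.is_clean for r in self.assess(X)], dtype=bool)

    def decision_function(self, X) -> np.ndarray:
        return np.array([r.severity for r in self.assess(X)])
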