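"""End-to-end per-window rhythm classification.

Mirrors the staged smartwatch algorithm: (1) motion-noise screening on
PPG time-frequency features gated by accelerometer amplitude; (2) pulse
peak detection and RR derivation on clean windows; (3) SampEn/RMSSD
fusion (Comb) against the 0.94 threshold to flag irregular windows;
(4) Poincare periodicity analysis of irregular windows to salvage
bigeminal/trigeminal/quadrigeminal ectopy from the AF bucket. Windows
rejected at stage 1, or with too few usable beats for the statistics,
are labelled NOISE.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .afdetect import COMB_K, COMB_THRESHOLD, IrregularRhythmDetector
from .ectopy import PATTERN_THRESHOLD, EctopyDetector, PoincareResult, salvage
from .errors import UnanalyzableSegmentError
from .mna import SEVERITY_THRESHOLD, MotionArtifactDetector
from .preprocess import PreprocessConfig, extract_rr
from .records import Segment


class PulseRhythmPipeline(BaseEstimator):
    """Segments in, {AF, PAC_PVC, NSR, NOISE} labels out.

    Composes the three estimators; every threshold is an __init__
    parameter so the whole pipeline plays with sklearn's get_params /
    set_params and clone. ``predict`` returns the label array;
    ``annotate`` additionally returns the per-window label table and
    intermediate results.
    """

    def __init__(
        self,
        mna_threshold: float = SEVERITY_THRESHOLD,
        accel_gate: float = 0.1,
        comb_threshold: float = COMB_THRESHOLD,
        comb_k: float = COMB_K,
        m: int = 1,
        r_fraction: float = 0.1,
        r_reference: str = "mean_rr",
        pattern_threshold: float = PATTERN_THRESHOLD,
        preprocess: PreprocessConfig | None = None,
    ):
        self.mna_threshold = mna_threshold
        self.accel_gate = accel_gate
        self.comb_threshold = comb_threshold
        self.comb_k = comb_k
        self.m = m
        self.r_fraction = r_fraction
        self.r_reference = r_reference
        self.pattern_threshold = pattern_threshold
        self.preprocess = preprocess

    def fit(self, X=None, y=None):
        self.mna_ = MotionArtifactDetector(
            accel_gate=self.accel_gate, threshold=self.mna_threshold
        ).fit()
        self.rhythm_ = IrregularRhythmDetector(
            m=self.m,
            r_fraction=self.r_fraction,
            r_reference=self.r_reference,
            comb_threshold=self.comb_threshold,
            comb_k=self.comb_k,
        ).fit()
        self.ectopy_ = EctopyDetector(threshold=self.pattern_threshold).fit()
        self.preprocess_ = self.preprocess or PreprocessConfig()
        return self

    def annotate(self, segments: list[Segment]) -> pd.DataFrame:
        """Full staged analysis; one labelled row per input segment."""
        if not hasattr(self, "mna_"):
            self.fit()
        window_rows = []
        for seg in segments:
            row = {
                "subject_id": seg.subject_id or "anon",
                "window_index": seg.window_index,
                "window_start": seg.window_start,
                "is_clean": False,
                "irregular": None,
                "ectopy": None,
                "features": None,
                "mna": None,
                "rr": None,
            }
            mna_res = self.mna_.assess([seg])[0]
            row["mna"] = mna_res
            row["is_clean"] = mna_res.is_clean
            if mna_res.is_clean:
                try:
                    rr = extract_rr(seg.ppg_slice, seg.ppg_rate, self.preprocess_)
                    feats = self.rhythm_.transform([rr])[0]
                except UnanalyzableSegmentError:
                    row["is_clean"] = False  # degenerate: counts as NOISE
                else:
                    row["rr"] = rr
                    row["features"] = feats
                    row["irregular"] = feats.irregular
                    if feats.irregular:
                        try:
                            row["ectopy"] = self.ectopy_.analyze([rr])[0]
                        except UnanalyzableSegmentError:
                            # too few beats to test periodicity: stays AF
                            row["ectopy"] = PoincareResult(
                                points=np.empty((0, 2)),
                                pattern="none",
                                periodicity_scores={},
                                n_clusters=1,
                            )
            window_rows.append(row)
        labels = salvage(window_rows)
        out = labels.copy()
        out["severity"] = [w["mna"].severity for w in window_rows]
        out["comb"] = [
            w["features"].comb if w["features"] is not None else np.nan
            for w in window_rows
        ]
        return out

    def predict(self, segments: list[Segment]) -> np.ndarray:
        return self.annotate(segments)["label"].to_numpy(dtype=object)


def classify_segments(segments: list[Segment], **params) -> pd.DataFrame:
    """Functional entry point over :class:`PulseRhythmPipeline`."""
    return PulseRhythmPipeline(**params).fit().annotate(segments)
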