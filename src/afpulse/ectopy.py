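"""Poincare-plot ectopic-beat (PAC/PVC) discrimination.

Premature atrial/ventricular contractions in bigeminal, trigeminal or
quadrigeminal patterns make the RR sequence *periodically* irregular:
the Poincare scatter of (RR_{i-1}, RR_i) collapses onto a few
off-diagonal clusters, whereas AF scatters diffusely. Folding the RR
sequence at a candidate period p and comparing within-phase spread to
total spread gives, per period, a score in [0, 1]:

    score(p) = 1 - mean_p(within-phase variance) / total variance

An exact period-p pattern scores 1; serially independent (AF-like) RR
scores near 0. A pattern is declared when the best score among
p in {2, 3, 4} exceeds the decision threshold (ties broken toward the
smaller period). This runs only on windows already flagged irregular,
salvaging benign ectopy from the AF bucket.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ConsistencyError, UnanalyzableSegmentError
from .records import RrSeries, make_label_table

#: Candidate ectopy periods: bigeminy, trigeminy, quadrigeminy.
PERIODS = (2, 3, 4)

PATTERN_NAME = {0: "none", 2: "bigeminy", 3: "trigeminy", 4: "quadrigeminy"}

#: Default decision threshold on the periodicity score.
PATTERN_THRESHOLD = 0.7


@dataclass
class PoincareResult:
    """Poincare points, per-period scores and the detected pattern."""

    points: np.ndarray  # (n-1, 2) pairs (RR_{i-1}, RR_i), ms
    pattern: str  # one of {none, bigeminy, trigeminy, quadrigeminy}
    periodicity_scores: dict  # period -> score in [0, 1]
    n_clusters: int  # detected period, 1 when no pattern


def _intervals(rr) -> np.ndarray:
    if isinstance(rr, RrSeries):
        return np.asarray(rr.rr_intervals, dtype=float)
    return np.asarray(rr, dtype=float)


def poincare_points(rr) -> np.ndarray:
    """Pairs (RR_{i-1}, RR_i) in original order; needs >= 4 intervals."""
    x = _intervals(rr)
    if x.size < 4:
        raise UnanalyzableSegmentError("Poincare plot needs >= 4 RR intervals")
    return np.column_stack([x[:-1], x[1:]])


def periodicity_scores(rr, periods=PERIODS) -> dict:
    """Variance-decomposition periodicity score per candidate period.

    For each period p the sequence is folded into p phase groups;
    score(p) = 1 - mean within-phase variance / total variance (both
    population variances). Scale-invariant; a constant sequence (zero
    total variance) scores 0 for every period by convention.
    """
    x = _intervals(rr)
    need = 2 * max(periods) + 2
    if x.size < need:
        raise UnanalyzableSegmentError(
            f"periodicity scores need >= {need} intervals, got {x.size}"
        )
    total = float(np.var(x))
    scores = {}
    for p in periods:
        if total == 0:
            scores[p] = 0.0
            continue
        within = np.mean([np.var(x[k::p]) for k in range(p)])
        scores[p] = float(max(0.0, 1.0 - within / total))
    return scores


def detect_ectopy(
    rr,
    threshold: float = PATTERN_THRESHOLD,
    periods=PERIODS,
    tie_epsilon: float = 0.02,
) -> PoincareResult:
    """Decide whether an irregular window shows a periodic ectopic
    pattern rather than AF.

    The winning period is the smallest period whose score both exceeds
    the threshold and comes within ``tie_epsilon`` of the best passing
    score; ``pattern`` is ``"none"`` when no score passes. The epsilon
    handles period nesting: an exact period-2 alternation is explained
    equally well by period 4 (up to sampling noise in the within-phase
    variances), and the parsimonious period is the physiological one.
    """
    points = poincare_points(rr)
    scores = periodicity_scores(rr, periods)
    passing = {p: s for p, s in scores.items() if s > threshold}
    best_p = 0
    if passing:
        top = max(passing.values())
        best_p = min(p for p, s in passing.items() if s >= top - tie_epsilon)
    return PoincareResult(
        points=points,
        pattern=PATTERN_NAME[best_p],
        periodicity_scores=scores,
        n_clusters=best_p if best_p else 1,
    )


def salvage(windows) -> pd.DataFrame:
    """Assemble final per-window labels from the staged decisions.

    ``windows`` is an iterable of dicts with keys ``subject_id``,
    ``window_index``, ``window_start``, ``is_clean`` (MNA), ``irregular``
    (Comb decision; may be None when unanalyzable) and ``ectopy``
    (:class:`PoincareResult` or None). The mapping is exhaustive and
    exclusive:

    * MNA-rejected or unanalyzable -> NOISE
    * irregular with a detected pattern -> PAC_PVC (salvaged)
    * irregular without a pattern -> AF
    * not irregular -> NSR

    A clean, irregular window without an ectopy result raises
    :class:`ConsistencyError` (the two-step order is mandatory).
    """
    rows = []
    for w in windows:
        if not w["is_clean"] or w.get("irregular") is None:
            label = "NOISE"
        elif w["irregular"]:
            ect = w.get("ectopy")
            if ect is None:
                raise ConsistencyError(
                    f"window {w['window_index']}: irregular but no ectopy result"
                )
            label = "PAC_PVC" if ect.pattern != "none" else "AF"
        else:
            label = "NSR"
        rows.append((w["subject_id"], w["window_index"], w["window_start"], label))
    return make_label_table(rows)


class EctopyDetector(BaseEstimator):
    """sklearn-style wrapper over :func:`detect_ectopy`: ``predict``
    maps RR series to pattern names."""

    def __init__(self, threshold: float = PATTERN_THRESHOLD, periods=PERIODS):
        self.threshold = threshold
        self.periods = periods

    def fit(self, X=None, y=None):
        self.threshold_ = float(self.threshold)
        return self

    def analyze(self, X) -> list[PoincareResult]:
        if not hasattr(self, "threshold_"):
            self.fit()
        return [detect_ectopy(rr, self.threshold_, self.periods) for rr in X]

    def predict(self, X) -> np.ndarray:
        return np.array([r.pattern for r in self.analyze(X)], dtype=object)
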