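"""Irregular-pulse (AF-candidate) discrimination from an RR series.

Two validated short-term variability statistics are fused into a single
decision value:

* sample entropy SampEn(m, r) = -ln(A/B), where B counts length-m
  template matches of the RR sequence under Chebyshev distance <= r
  (self-matches excluded) and A the length-(m+1) matches — the
  complexity of pulse variability;
* RMSSD, the root mean square of successive RR differences, normalized
  by the mean RR to make it heart-rate robust.

The fusion is Comb = SampEn * (1 + k * RMSSD/meanRR), monotone
non-decreasing in both inputs, and a window is flagged *irregular*
when Comb strictly exceeds the 0.94 decision threshold.

The entropy tolerance r is *absolute*, defaulting to 0.1x the window's
mean RR. On 30-beat windows a tolerance tied to the window SD makes
SampEn nearly scale-invariant — it then measures only pattern
complexity, which such short windows cannot resolve — whereas an
absolute tolerance keeps the beat-to-beat *amplitude* information that
separates AF from sinus rhythm (the same reasoning behind
fixed-tolerance entropies for very short RR series, e.g. COSEn). When
no length-(m+1) template pair matches (A = 0) the entropy is unbounded
and the window is treated as maximally irregular (Comb = +inf).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .errors import ParameterError, UnanalyzableSegmentError
from .records import RrSeries

#: Decision threshold on the fused statistic.
COMB_THRESHOLD = 0.94

#: Fusion gain on normalized RMSSD; calibrated on the synthetic corpora
#: (see docs/methods.md) so the 0.94 threshold separates AF from NSR.
COMB_K = 10.0


@dataclass
class FeatureParams:
    """Parameters of the rhythm-discrimination statistics.

    m : template length for sample entropy (beats).
    r_fraction : entropy tolerance as a fraction of the reference scale.
    r_reference : scale the tolerance multiplies — ``"mean_rr"``
        (absolute tolerance, default) or ``"sd"`` (the classic
        SD-relative convention, retained for comparison).
    comb_threshold : decision threshold on the fused statistic.
    comb_k : fusion gain multiplying normalized RMSSD.
    rmssd_normalization : divide RMSSD by mean RR before fusing.
    """

    m: int = 1
    r_fraction: float = 0.1
    r_reference: str = "mean_rr"
    comb_threshold: float = COMB_THRESHOLD
    comb_k: float = COMB_K
    rmssd_normalization: bool = True

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ParameterError("m must be >= 1")
        if self.r_fraction <= 0:
            raise ParameterError("r_fraction must be positive")
        if self.r_reference not in ("mean_rr", "sd"):
            raise ParameterError("r_reference must be 'mean_rr' or 'sd'")
        if self.comb_threshold <= 0:
            raise ParameterError("comb_threshold must be positive")

    def tolerance(self, rr_intervals: np.ndarray) -> float:
        """Absolute entropy tolerance in ms for one window."""
        scale = (
            float(np.mean(rr_intervals))
            if self.r_reference == "mean_rr"
            else float(np.std(rr_intervals))
        )
        return self.r_fraction * scale if scale > 0 else 1e-9


@dataclass
class FeatureSet:
    """Per-window rhythm features and the irregularity decision."""

    sampen: float
    rmssd: float  # ms
    rmssd_norm: float  # dimensionless
    comb: float
    irregular: bool


def _intervals(rr) -> np.ndarray:
    if isinstance(rr, RrSeries):
        arr = rr.rr_intervals
    else:
        arr = np.asarray(rr, dtype=float)
    return np.asarray(arr, dtype=float)


def rmssd(rr) -> float:
    """Root mean square of successive RR differences, in ms.

    Requires at least 3 intervals (2 successive differences would be the
    bare minimum for a *mean* square; 3 keeps the statistic stable).
    """
    x = _intervals(rr)
    if x.size < 3:
        raise UnanalyzableSegmentError("RMSSD needs >= 3 RR intervals")
    d = np.diff(x)
    return float(np.sqrt(np.mean(d**2)))


def sample_entropy(rr, m: int = 1, r: float | None = None) -> float:
    """SampEn(m, r) of an RR series: -ln(A/B) with self-matches excluded.

    ``r`` is an absolute tolerance in ms; when omitted it defaults to
    0.2x the series SD. Returns ``math.inf`` when no (m+1)-templates
    match (A = 0) — downstream treats that as maximal irregularity. B = 0
    (no m-template matches at all) also maps to ``math.inf``.
    """
    x = _intervals(rr)
    if m < 1:
        raise ParameterError("m must be >= 1")
    n = x.size
    if n < m + 2:
        raise UnanalyzableSegmentError(
            f"sample entropy needs >= {m + 2} intervals, got {n}"
        )
    if r is None:
        r = 0.2 * float(np.std(x))
    if r <= 0:
        raise ParameterError("tolerance r must be positive")

    # Convention: both template sets are truncated to n - m vectors so B
    # and A count over the same index range (standard SampEn definition).
    n_b = n - m
    templates_m = np.lib.stride_tricks.sliding_window_view(x, m)[:n_b]
    diff_b = np.abs(templates_m[:, None, :] - templates_m[None, :, :]).max(axis=2)
    b = int((np.sum(diff_b <= r) - n_b) // 2)
    templates_m1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)
    diff_a = np.abs(templates_m1[:, None, :] - templates_m1[None, :, :]).max(axis=2)
    n_a = templates_m1.shape[0]
    a = int((np.sum(diff_a <= r) - n_a) // 2)

    if b == 0 or a == 0:
        return math.inf
    return float(-math.log(a / b))


def comb(sampen: float, rmssd_norm: float, params: FeatureParams | None = None) -> float:
    """Fused decision statistic: ``sampen * (1 + k * rmssd_norm)``.

    Monotone non-decreasing in both inputs; zero entropy gives zero Comb
    regardless of RMSSD, and infinite entropy propagates.
    """
    p = params or FeatureParams()
    if not rmssd_norm >= 0:
        raise ParameterError("rmssd_norm must be finite and >= 0")
    if sampen < 0:
        raise ParameterError("sampen must be >= 0")
    if math.isinf(sampen):
        return math.inf
    return float(sampen * (1.0 + p.comb_k * rmssd_norm))


def is_irregular(comb_value: float, params: FeatureParams | None = None) -> bool:
    """Decision rule on the fused statistic: irregular iff Comb strictly
    exceeds the threshold (a tie at the threshold is regular)."""
    p = params or FeatureParams()
    return bool(comb_value > p.comb_threshold)


def classify_window(rr, params: FeatureParams | None = None) -> FeatureSet:
    """Compute SampEn, RMSSD and Comb for one clean window and flag it
    irregular when Comb strictly exceeds the threshold (a tie at the
    threshold is *not* irregular)."""
    p = params or FeatureParams()
    x = _intervals(rr)
    se = sample_entropy(x, m=p.m, r=p.tolerance(x))
    rm = rmssd(x)
    mean_rr = float(np.mean(x))
    rm_norm = rm / mean_rr if p.rmssd_normalization else rm
    c = comb(se, rm_norm, p)
    return FeatureSet(
        sampen=se,
        rmssd=rm,
        rmssd_norm=rm_norm,
        comb=c,
        irregular=is_irregular(c, p),
    )


class IrregularRhythmDetector(BaseEstimator):
    """Rule-based irregular-pulse classifier over per-window RR series.

    Parameters mirror :class:`FeatureParams`. ``fit`` validates the
    parameters (there is nothing to learn — the thresholds are part of
    the method); ``predict`` maps a sequence of RR series to booleans and
    ``decision_function`` returns the Comb values (minus the threshold,
    sklearn-style: positive means irregular).
    """

    def __init__(
        self,
        m: int = 1,
        r_fraction: float = 0.1,
        r_reference: str = "mean_rr",
        comb_threshold: float = COMB_THRESHOLD,
        comb_k: float = COMB_K,
        rmssd_normalization: bool = True,
    ):
        self.m = m
        self.r_fraction = r_fraction
        self.r_reference = r_reference
        self.comb_threshold = comb_threshold
        self.comb_k = comb_k
        self.rmssd_normalization = rmssd_normalization

    def _params(self) -> FeatureParams:
        return FeatureParams(
            m=self.m,
            r_fraction=self.r_fraction,
            r_reference=self.r_reference,
            comb_threshold=self.comb_threshold,
            comb_k=self.comb_k,
            rmssd_normalization=self.rmssd_normalization,
        )

    def fit(self, X=None, y=None):
        self.params_ = self._params()
        return self

    def transform(self, X) -> list[FeatureSet]:
        """Full feature sets for a sequence of RR series."""
        if not hasattr(self, "params_"):
            self.fit()
        return [classify_window(rr, self.params_) for rr in X]

    def predict(self, X) -> np.ndarray:
        """Boolean irregular flags for a sequence of RR series."""
        return np.array([f.irregular for f in self.transform(X)], dtype=bool)

    def decision_function(self, X) -> np.ndarray:
        return np.array(
            [f.comb - self.params_.comb_threshold for f in self.transform(X)]
        )
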