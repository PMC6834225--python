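"""Diagnostic-accuracy evaluation of per-window rhythm labels.

The comparison is the AF vs non-AF dichotomy: PAC_PVC and NSR both count
as the negative (non-AF) class, and NOISE windows are excluded from the
matrix on both sides — only noise-free windows are evaluable. Metrics
are percentages; for reporting they are rounded to one decimal place
(half away from zero). A zero-denominator metric is *not available*
(None), never 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .errors import AlignmentError
from .records import validate_label_table


@dataclass
class ConfusionSummary:
    """2x2 confusion counts (positive class = AF) and derived metrics.

    Metric attributes hold full-precision percentages or None when the
    denominator is zero; use :meth:`rounded` for one-decimal reporting.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return 100.0 * self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return 100.0 * self.tn / d if d else None

    @property
    def accuracy(self) -> float | None:
        return 100.0 * (self.tp + self.tn) / self.n if self.n else None

    @property
    def ppv(self) -> float | None:
        d = self.tp + self.fp
        return 100.0 * self.tp / d if d else None

    @property
    def npv(self) -> float | None:
        d = self.tn + self.fn
        return 100.0 * self.tn / d if d else None

    METRICS = ("sensitivity", "specificity", "accuracy", "ppv", "npv")

    def rounded(self) -> dict:
        """Metrics rounded to one decimal, half away from zero (the
        printed convention); None stays None."""
        out = {}
        for name in self.METRICS:
            v = getattr(self, name)
            out[name] = (
                float(Decimal(repr(v)).quantize(Decimal("0.1"), ROUND_HALF_UP))
                if v is not None
                else None
            )
        return out


def confusion(
    pred: pd.DataFrame, ref: pd.DataFrame, *, intersect: bool = False
) -> ConfusionSummary:
    """Confusion summary of predicted vs reference label tables.

    Both tables are validated and NOISE windows are dropped from *both*
    sides. By default the remaining (subject_id, window_index) key sets
    must then match exactly — otherwise :class:`AlignmentError`. With
    ``intersect=True`` the comparison is restricted to windows that are
    noise-free on both sides (the study convention: windows the pulse
    algorithm rejects as noisy are excluded from evaluation even though
    the ECG reference labels them).
    """
    pred = validate_label_table(pred)
    ref = validate_label_table(ref)
    keys = ["subject_id", "window_index"]
    pred = pred[pred["label"] != "NOISE"]
    ref = ref[ref["label"] != "NOISE"]
    how = "inner" if intersect else "outer"
    merged = pred.merge(ref, on=keys, how=how, suffixes=("_pred", "_ref"))
    if merged["label_pred"].isna().any() or merged["label_ref"].isna().any():
        raise AlignmentError(
            "predicted and reference tables cover different noise-free windows"
        )
    p_af = merged["label_pred"] == "AF"
    r_af = merged["label_ref"] == "AF"
    return ConfusionSummary(
        tp=int((p_af & r_af).sum()),
        fp=int((p_af & ~r_af).sum()),
        fn=int((~p_af & r_af).sum()),
        tn=int((~p_af & ~r_af).sum()),
    )


def report(summary: ConfusionSummary, path) -> pd.DataFrame:
    """Write counts + rounded metrics as CSV (and return the frame).

    The CSV round-trips the counts losslessly; metric cells hold the
    one-decimal strings or ``NA`` when undefined.
    """
    rounded = summary.rounded()
    rows = [("tp", summary.tp), ("fp", summary.fp), ("fn", summary.fn), ("tn", summary.tn)]
    rows += [
        (name, "NA" if rounded[name] is None else f"{rounded[name]:.1f}")
        for name in ConfusionSummary.METRICS
    ]
    df = pd.DataFrame(rows, columns=["quantity", "value"])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return df


def read_report(path) -> ConfusionSummary:
    """Recover a :class:`ConfusionSummary` from a report CSV (counts only
    — metrics are re-derived, which is the internal-consistency check)."""
    df = pd.read_csv(path).set_index("quantity")["value"]
    return ConfusionSummary(
        tp=int(df["tp"]), fp=int(df["fp"]), fn=int(df["fn"]), tn=int(df["tn"])
    )
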