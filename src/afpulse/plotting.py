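"""Optional diagnostic figures: detected peaks over the filtered pulse
waveform, and the Poincare scatter of an RR series."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .ectopy import poincare_points
from .records import RrSeries


def plot_peaks(filtered, sampling_rate: float, peak_indices, path) -> None:
    """PPG trace with detected pulse peaks marked; saved as PNG."""
    x = np.asarray(filtered, dtype=float)
    t = np.arange(x.size) / sampling_rate
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.plot(t, x, lw=0.8, color="tab:blue")
    pk = np.asarray(peak_indices, dtype=float)
    ax.plot(pk / sampling_rate, np.interp(pk, np.arange(x.size), x), "rv", ms=5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("PPG (filtered, a.u.)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_poincare(rr: RrSeries, path, title: str = "") -> None:
    """Scatter of each RR interval against its predecessor (ms)."""
    pts = poincare_points(rr)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(pts[:, 0], pts[:, 1], s=12, alpha=0.7)
    lim = (min(pts.min(), 300.0) - 50, max(pts.max(), 1200.0) + 50)
    ax.plot(lim, lim, "k--", lw=0.6)
    ax.set_xlim(lim)
    ax.set_ylim(lim)
    ax.set_xlabel(r"RR$_{i-1}$ (ms)")
    ax.set_ylabel(r"RR$_i$ (ms)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
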