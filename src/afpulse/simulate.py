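"""Seeded generator of ground-truth-labelled synthetic pulse data.

The generator emulates the four rhythm states a wrist PPG study of older
cardiology patients encounters, plus scripted motion scenarios:

* NSR — mean RR = 60000/HR with AR(1)-correlated Gaussian deviations and
  a sinusoidal respiratory modulation (respiratory sinus arrhythmia).
* AF — serially independent RR drawn from a standardized shifted
  log-normal (long right tail), scaled to a stated SD: high beat-to-beat
  entropy, no autocorrelation.
* BIGEMINY / TRIGEMINY / QUADRIGEMINY — NSR base with every p-th beat
  premature (coupling interval shortened by ``prematurity_fraction``)
  followed by a compensatory pause, with Gaussian phase jitter.
* Motion scenarios — additive band-limited artifact at gait/arm
  frequencies on the PPG plus a synchronized tri-axial accelerometer
  record whose gravity-removed RMS follows the scenario intensity
  ordering still < slow_walk < fast_walk <= arm_movement <= stairs.

Everything is driven by one integer seed; a fixed seed reproduces the
corpus byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .errors import ConfigError, ParameterError
from .io import write_accel, write_ppg
from .records import AccelRecord, PpgRecord, RrSeries, make_label_table

RHYTHMS = ("NSR", "AF", "BIGEMINY", "TRIGEMINY", "QUADRIGEMINY")
SCENARIOS = ("still", "slow_walk", "fast_walk", "arm_movement", "stairs")

#: Ectopy period per rhythm name (every p-th beat premature).
ECTOPY_PERIOD = {"BIGEMINY": 2, "TRIGEMINY": 3, "QUADRIGEMINY": 4}

#: Ground-truth window label implied by each rhythm class.
TRUE_LABEL = {
    "NSR": "NSR",
    "AF": "AF",
    "BIGEMINY": "PAC_PVC",
    "TRIGEMINY": "PAC_PVC",
    "QUADRIGEMINY": "PAC_PVC",
}

#: Scenario -> (PPG artifact amplitude relative to unit pulse amplitude,
#: artifact band Hz, target gravity-removed accelerometer RMS in g).
SCENARIO_PARAMS = {
    "still": (0.0, (0.5, 2.0), 0.003),
    "slow_walk": (0.8, (0.8, 2.2), 0.15),
    "fast_walk": (1.8, (1.5, 3.5), 0.25),
    "arm_movement": (2.2, (0.5, 2.5), 0.35),
    "stairs": (2.5, (1.0, 3.5), 0.5),
}

RR_CLIP = (300.0, 2000.0)  # physiologic clip applied to every simulated series


@dataclass
class SimulationConfig:
    """Parameters of one simulated window/record.

    Defaults encode a moderate-HRV older adult: HR 70 bpm, NSR SDNN
    30 ms, AF beat-to-beat SD 150 ms, 35% premature-beat coupling
    shortening with 15 ms phase jitter, PPG at 100 Hz and accelerometer
    at 50 Hz.
    """

    rhythm: str = "NSR"
    duration: float = 30.0  # seconds
    heart_rate: float = 70.0  # bpm
    hrv_sd: float = 30.0  # ms, NSR deviation SD
    ar_coeff: float = 0.9  # AR(1) coefficient of NSR deviations
    resp_amp: float = 10.0  # ms, respiratory modulation amplitude
    resp_freq: float = 0.25  # Hz
    af_variability: float = 150.0  # ms, AF RR SD
    prematurity_fraction: float = 0.35
    compensatory_factor: float = 1.0  # full compensatory pause: the next
    # sinus beat arrives on schedule, so the cycle length (and the mean
    # heart rate) is preserved exactly
    jitter_sd: float = 15.0  # ms
    noise_scenario: str = "still"
    ppg_rate: float = 100.0  # Hz
    accel_rate: float = 50.0  # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rhythm not in RHYTHMS:
            raise ConfigError(f"unknown rhythm {self.rhythm!r}")
        if self.noise_scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario {self.noise_scenario!r}")
        if self.duration <= 0:
            raise ConfigError("duration must be positive")
        if not 30 <= self.heart_rate <= 220:
            raise ConfigError("heart_rate must be in [30, 220] bpm")
        mean_rr = 60000.0 / self.heart_rate
        if not RR_CLIP[0] <= mean_rr <= RR_CLIP[1]:
            raise ConfigError(f"mean RR {mean_rr:.0f} ms outside {RR_CLIP}")


def _standardized_lognormal(rng: np.random.Generator, n: int, sigma: float = 0.5):
    """Log-normal draws shifted/scaled to zero mean, unit SD (long right
    tail preserved)."""
    raw = rng.lognormal(mean=0.0, sigma=sigma, size=n)
    mu = np.exp(sigma**2 / 2)
    sd = np.sqrt((np.exp(sigma**2) - 1) * np.exp(sigma**2))
    return (raw - mu) / sd


def simulate_rr(config: SimulationConfig) -> RrSeries:
    """Generate one ground-truth RR series for the configured rhythm.

    The returned ``peak_times`` are the true beat times (seconds from the
    window start, first beat at a small random offset) and
    ``rr_intervals`` their successive differences in ms after clipping to
    physiologic range.
    """
    rng = np.random.default_rng(config.seed)
    mean_rr = 60000.0 / config.heart_rate
    # generous beat budget, trimmed to duration below
    n = int(np.ceil(config.duration * 1000.0 / max(mean_rr * 0.5, RR_CLIP[0]))) + 8

    if config.rhythm == "AF":
        rr = mean_rr + config.af_variability * _standardized_lognormal(rng, n)
    else:
        # AR(1) deviations with stationary SD = hrv_sd
        innov_sd = config.hrv_sd * np.sqrt(1.0 - config.ar_coeff**2)
        dev = np.empty(n)
        dev[0] = rng.normal(0.0, config.hrv_sd)
        eps = rng.normal(0.0, innov_sd, size=n - 1)
        for i in range(1, n):
            dev[i] = config.ar_coeff * dev[i - 1] + eps[i - 1]
        rr = mean_rr + dev
        if config.rhythm in ECTOPY_PERIOD:
            p = ECTOPY_PERIOD[config.rhythm]
            short = config.prematurity_fraction * mean_rr
            # every p-th beat premature, the following interval is the
            # compensatory pause; phase chosen so the sequence has exact
            # global period p (..., N, short, pause, N, short, pause, ...)
            prem = np.arange(p - 2 if p > 2 else 0, n - 1, p)
            rr[prem] -= short
            rr[prem + 1] += config.compensatory_factor * short
            if config.jitter_sd > 0:
                rr += rng.normal(0.0, config.jitter_sd, size=n)

    rr = np.clip(rr, *RR_CLIP)
    t0 = rng.uniform(0.2, 0.8)  # first beat offset inside the window
    beat_times = t0 + np.concatenate([[0.0], np.cumsum(rr)]) / 1000.0

    if config.rhythm == "NSR":
        # respiratory sinus arrhythmia: smooth sinusoidal modulation of
        # beat timing, applied in time so RR picks up the derivative
        beat_times = beat_times + (config.resp_amp / 1000.0) * np.sin(
            2 * np.pi * config.resp_freq * beat_times
        )

    beat_times = beat_times[beat_times < config.duration]
    if beat_times.size < 3:
        raise ConfigError("configuration yields fewer than 3 beats per window")
    rr_out = np.diff(beat_times) * 1000.0
    rr_out = np.clip(rr_out, *RR_CLIP)
    return RrSeries(peak_times=beat_times, rr_intervals=rr_out)


def rr_to_ppg(rr: RrSeries, ppg_rate: float, duration: float | None = None) -> np.ndarray:
    """Render beat times as a stereotyped pulse waveform.

    Each beat contributes a primary systolic wave (Gaussian centred at the
    beat time) plus a smaller, delayed dicrotic wave; both widths scale
    with the local RR so morphology stays realistic across heart rates.
    The output is amplitude-normalized to peak 1.
    """
    beats = np.asarray(rr.peak_times, dtype=float)
    if duration is None:
        duration = float(beats[-1] + 1.0) if beats.size else 1.0
    n = int(round(duration * ppg_rate))
    t = np.arange(n) / ppg_rate
    x = np.zeros(n)
    if beats.size == 0:
        return x
    # local RR per beat (s): mean of adjacent intervals, edge-padded
    local = np.empty(beats.size)
    if beats.size > 1:
        d = np.diff(beats)
        local[0] = d[0]
        local[-1] = d[-1]
        if beats.size > 2:
            local[1:-1] = 0.5 * (d[:-1] + d[1:])
    else:
        local[:] = 0.85
    for b, T in zip(beats, local):
        sig1 = 0.09 * T
        sig2 = 0.14 * T
        lo = max(int((b - 0.6 * T) * ppg_rate), 0)
        hi = min(int((b + 0.9 * T) * ppg_rate) + 1, n)
        tt = t[lo:hi]
        x[lo:hi] += np.exp(-0.5 * ((tt - b) / sig1) ** 2)
        x[lo:hi] += 0.3 * np.exp(-0.5 * ((tt - b - 0.35 * T) / sig2) ** 2)
    peak = np.max(np.abs(x))
    return x / peak if peak > 0 else x


def _bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-RMS noise restricted to ``band`` (4th-order Butterworth on
    white Gaussian noise)."""
    lo, hi = band
    hi = min(hi, 0.45 * fs)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n + int(4 * fs)))[int(4 * fs) :]
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def corrupt(
    ppg: np.ndarray,
    scenario: str,
    seed: int,
    ppg_rate: float = 100.0,
    accel_rate: float = 50.0,
    subject_id: str = "",
    start_time: float = 0.0,
) -> tuple[np.ndarray, AccelRecord]:
    """Add scenario-specific motion artifact to a PPG series and produce
    the synchronized accelerometer record.

    ``still`` leaves the PPG untouched (sensor-floor accelerometer noise
    only); the other scenarios add band-limited oscillatory artifact whose
    amplitude and the matching accelerometer RMS follow the scripted-ADL
    intensity ordering.
    """
    if scenario not in SCENARIOS:
        raise ParameterError(f"unknown scenario {scenario!r}")
    amp, band, accel_rms = SCENARIO_PARAMS[scenario]
    rng = np.random.default_rng(seed)
    ppg = np.asarray(ppg, dtype=float)
    duration = ppg.size / ppg_rate

    if amp > 0:
        artifact = amp * _bandlimited_noise(rng, ppg.size, ppg_rate, band)
        corrupted = ppg + artifact
    else:
        corrupted = ppg.copy()

    n_acc = int(round(duration * accel_rate))
    axes = []
    for _ in range(3):
        a = _bandlimited_noise(rng, n_acc, accel_rate, band)
        axes.append(a)
    axes = np.array(axes)
    # scale so the gravity-removed vector RMS hits the scenario target
    vec_rms = np.sqrt(np.mean(np.sum(axes**2, axis=0)))
    axes *= accel_rms / vec_rms
    accel = AccelRecord(
        subject_id=subject_id,
        sampling_rate=accel_rate,
        start_time=start_time,
        x=axes[0],
        y=axes[1],
        z=axes[2] + 1.0,  # gravity on z
    )
    return corrupted, accel


def simulate_window(config: SimulationConfig):
    """One labelled window: (ppg samples, AccelRecord, RrSeries, label).

    The label is the ground-truth designation the pipeline should emit:
    the rhythm's own label for ``still`` windows, NOISE for motion
    scenarios (their artifact is constructed to defeat pulse analysis).
    """
    rr = simulate_rr(config)
    clean = rr_to_ppg(rr, config.ppg_rate, config.duration)
    ppg, accel = corrupt(
        clean,
        config.noise_scenario,
        seed=config.seed + 1,
        ppg_rate=config.ppg_rate,
        accel_rate=config.accel_rate,
    )
    label = TRUE_LABEL[config.rhythm] if config.noise_scenario == "still" else "NOISE"
    return ppg, accel, rr, label


def windows_to_segments(windows) -> list:
    """Package corpus windows as :class:`~afpulse.records.Segment`
    objects ready for the analysis pipeline."""
    from .records import Segment

    segments = []
    for w in windows:
        cfg = w["config"]
        segments.append(
            Segment(
                window_index=w["window_index"],
                window_start=float(w["window_index"] * cfg.duration),
                window_length=cfg.duration,
                ppg_slice=w["ppg"],
                accel_slice=w["accel"].xyz(),
                ppg_rate=cfg.ppg_rate,
                accel_rate=cfg.accel_rate,
                subject_id="sim",
            )
        )
    return segments


#: Default corpus composition: counts per (rhythm, scenario).
DEFAULT_CORPUS = (
    ("AF", "still", 200),
    ("NSR", "still", 200),
    ("BIGEMINY", "still", 20),
    ("TRIGEMINY", "still", 20),
    ("QUADRIGEMINY", "still", 20),
    ("NSR", "slow_walk", 25),
    ("NSR", "fast_walk", 25),
    ("NSR", "arm_movement", 25),
    ("AF", "stairs", 25),
)


def generate_corpus(
    spec=DEFAULT_CORPUS,
    seed: int = 0,
    out_dir=None,
    config_overrides: dict | None = None,
):
    """Generate a labelled corpus of independent 30-second windows.

    Returns ``(windows, truth)`` where ``windows`` is a list of
    ``(Segment-like dict, RrSeries)`` entries and ``truth`` a label
    table. When ``out_dir`` is given, also writes one PPG/accel CSV pair
    per window, the truth table, and a JSON manifest recording the spec
    and seed; output is byte-reproducible for a fixed seed.
    """
    spec = list(spec)
    if not spec:
        raise ParameterError("corpus spec must be non-empty")
    overrides = config_overrides or {}
    root = np.random.default_rng(seed)
    windows = []
    rows = []
    idx = 0
    for rhythm, scenario, count in spec:
        for _ in range(int(count)):
            wseed = int(root.integers(0, 2**31 - 1))
            cfg = SimulationConfig(
                rhythm=rhythm, noise_scenario=scenario, seed=wseed, **overrides
            )
            ppg, accel, rr, label = simulate_window(cfg)
            windows.append(
                {
                    "window_index": idx,
                    "rhythm": rhythm,
                    "scenario": scenario,
                    "ppg": ppg,
                    "accel": accel,
                    "rr": rr,
                    "config": cfg,
                }
            )
            rows.append(("sim", idx, float(idx * cfg.duration), label))
            idx += 1
    truth = make_label_table(rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for w in windows:
            cfg = w["config"]
            rec = PpgRecord(
                subject_id="sim",
                sampling_rate=cfg.ppg_rate,
                start_time=0.0,
                samples=w["ppg"],
            )
            write_ppg(out_dir / f"ppg_{w['window_index']:04d}.csv", rec)
            write_accel(out_dir / f"accel_{w['window_index']:04d}.csv", w["accel"])
        truth.to_csv(out_dir / "truth.csv", index=False)
        manifest = {
            "seed": int(seed),
            "spec": [[r, s, int(c)] for r, s, c in spec],
            "config_overrides": {k: v for k, v in overrides.items()},
            "defaults": {
                k: v for k, v in asdict(SimulationConfig()).items()
            },
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return windows, truth
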