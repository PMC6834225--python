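"""Shared fixtures: independent oracles and synthetic-window builders."""

from __future__ import annotations

import math

import numpy as np
import pytest

from afpulse.records import Segment
from afpulse.simulate import SimulationConfig, simulate_window


def sampen_bruteforce(x, m: int, r: float) -> float:
    """O(n^2) double-loop sample entropy, written directly from the
    definition: B counts pairs of length-m templates within Chebyshev
    distance r (self-matches excluded), A the length-(m+1) pairs, both
    over the first n-m template positions; SampEn = -ln(A/B)."""
    x = list(map(float, x))
    n = len(x)
    b = a = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    if a == 0 or b == 0:
        return math.inf
    return -math.log(a / b)


@pytest.fixture(scope="session")
def sampen_oracle():
    return sampen_bruteforce


def build_segment(config: SimulationConfig, window_index: int = 0) -> Segment:
    """One simulated 30-s Segment with its matched accelerometer slice."""
    ppg, accel, _, _ = simulate_window(config)
    return Segment(
        window_index=window_index,
        window_start=window_index * config.duration,
        window_length=config.duration,
        ppg_slice=ppg,
        accel_slice=accel.xyz(),
        ppg_rate=config.ppg_rate,
        accel_rate=config.accel_rate,
        subject_id="sim",
    )


@pytest.fixture(scope="session")
def make_segment():
    return build_segment


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
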