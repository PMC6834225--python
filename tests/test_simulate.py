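"""Synthetic rhythm/PPG/motion generator: construction guarantees."""

import numpy as np
import pytest

from afpulse.afdetect import rmssd, sample_entropy
from afpulse.errors import ConfigError
from afpulse.simulate import (
    SCENARIO_PARAMS,
    SimulationConfig,
    corrupt,
    generate_corpus,
    rr_to_ppg,
    simulate_rr,
)


class TestSimulateRr:
    def test_degenerate_nsr_constant(self):
        cfg = SimulationConfig(rhythm="NSR", heart_rate=75.0, hrv_sd=0.0,
                               resp_amp=0.0, seed=1)
        rr = simulate_rr(cfg)
        np.testing.assert_allclose(rr.rr_intervals, 800.0, rtol=1e-12)

    def test_af_no_serial_correlation(self):
        """Lag-1 autocorrelation of AF RR is near zero at n = 500."""
        cfg = SimulationConfig(rhythm="AF", duration=500.0, heart_rate=75.0, seed=2)
        x = simulate_rr(cfg).rr_intervals
        assert x.size >= 400
        xc = x - x.mean()
        rho = float(np.sum(xc[:-1] * xc[1:]) / np.sum(xc**2))
        assert abs(rho) < 0.1

    def test_bigeminy_exact_period_without_jitter(self):
        cfg = SimulationConfig(rhythm="BIGEMINY", heart_rate=70.0, hrv_sd=0.0,
                               jitter_sd=0.0, seed=3)
        x = simulate_rr(cfg).rr_intervals
        n = (x.size // 2) * 2
        assert np.allclose(x[: n - 2], x[2:n], rtol=1e-9)
        assert not np.allclose(x[:-1], x[1:])  # genuinely alternating

    def test_mean_rr_tracks_heart_rate(self):
        """Long-run mean RR is within 2% of 60000/HR for every rhythm.
        Per 30-s window the mean fluctuates by a few percent (AF draws
        and slowly-mixing AR(1) sinus deviations), so the
        construction-level check uses 20-minute series where 2% is a
        >4-sigma band."""
        root = np.random.default_rng(8)
        for rhythm in ("NSR", "AF", "BIGEMINY", "TRIGEMINY", "QUADRIGEMINY"):
            for _ in range(3):
                hr = float(root.uniform(50, 120))
                cfg = SimulationConfig(rhythm=rhythm, heart_rate=hr,
                                       duration=1200.0,
                                       seed=int(root.integers(2**31)))
                mean_rr = simulate_rr(cfg).mean_rr
                assert mean_rr == pytest.approx(60000.0 / hr, rel=0.02)

    def test_af_more_variable_than_nsr(self):
        """Simulated AF has higher SampEn and RMSSD than NSR at equal
        heart rate (median over 200 seeded windows each)."""
        root = np.random.default_rng(13)
        med = {}
        for rhythm in ("AF", "NSR"):
            ses, rms = [], []
            for _ in range(200):
                x = simulate_rr(
                    SimulationConfig(rhythm=rhythm, heart_rate=72.0,
                                     seed=int(root.integers(2**31)))
                ).rr_intervals
                se = sample_entropy(x, 1, 0.1 * float(np.mean(x)))
                ses.append(se if np.isfinite(se) else 10.0)
                rms.append(rmssd(x))
            med[rhythm] = (np.median(ses), np.median(rms))
        assert med["AF"][0] > med["NSR"][0]
        assert med["AF"][1] > med["NSR"][1]

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(heart_rate=20.0)
        with pytest.raises(ConfigError):
            SimulationConfig(rhythm="FLUTTER")
        with pytest.raises(ConfigError):
            SimulationConfig(noise_scenario="swim")


class TestRrToPpg:
    def test_maxima_align_with_beats(self):
        rr = simulate_rr(SimulationConfig(rhythm="NSR", heart_rate=80.0, seed=4))
        ppg = rr_to_ppg(rr, 100.0, 30.0)
        from scipy.signal import find_peaks

        idx, _ = find_peaks(ppg, height=0.5, distance=30)
        times = idx[idx / 100.0 < 29.5] / 100.0
        interior = rr.peak_times[rr.peak_times < 29.5]
        dev = np.abs(interior[:, None] - times[None, :]).min(axis=1)
        assert np.all(dev <= 0.020)
        assert times.size == interior.size

    def test_no_beats_flat(self):
        from afpulse.records import RrSeries

        empty = RrSeries(peak_times=np.array([]), rr_intervals=np.array([]))
        assert np.all(rr_to_ppg(empty, 100.0, 5.0) == 0.0)


class TestCorrupt:
    def test_still_leaves_ppg_unchanged(self):
        ppg = rr_to_ppg(simulate_rr(SimulationConfig(seed=5)), 100.0, 30.0)
        out, accel = corrupt(ppg, "still", seed=6)
        np.testing.assert_array_equal(out, ppg)
        mag = np.linalg.norm(
            accel.xyz() - accel.xyz().mean(axis=0), axis=1
        )
        assert np.sqrt(np.mean(mag**2)) < 0.01

    def test_scenario_intensity_ordering(self):
        """Artifact power and accelerometer RMS follow
        still < slow_walk < fast_walk <= arm_movement <= stairs."""
        ppg = rr_to_ppg(simulate_rr(SimulationConfig(seed=7)), 100.0, 30.0)
        power, arms = {}, {}
        for scen in SCENARIO_PARAMS:
            out, accel = corrupt(ppg, scen, seed=8)
            power[scen] = float(np.mean((out - ppg) ** 2))
            a = accel.xyz()
            a = a - a.mean(axis=0)
            arms[scen] = float(np.sqrt(np.mean(np.sum(a**2, axis=1))))
        order = ["still", "slow_walk", "fast_walk", "arm_movement", "stairs"]
        for a, b in zip(order, order[1:]):
            assert power[a] <= power[b]
            assert arms[a] < arms[b] + 1e-12


class TestGenerateCorpus:
    def test_truth_rows_match_spec(self):
        windows, truth = generate_corpus([("NSR", "still", 10)], seed=0)
        assert len(windows) == 10
        assert list(truth["label"].unique()) == ["NSR"]

    def test_fixed_seed_byte_identical(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        spec = [("AF", "still", 2), ("NSR", "slow_walk", 2)]
        generate_corpus(spec, seed=99, out_dir=d1)
        generate_corpus(spec, seed=99, out_dir=d2)
        files = sorted(p.name for p in d1.iterdir())
        assert files == sorted(p.name for p in d2.iterdir())
        for name in files:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_manifest_records_seed_and_spec(self, tmp_path):
        import json

        generate_corpus([("NSR", "still", 1)], seed=5, out_dir=tmp_path / "c")
        manifest = json.loads((tmp_path / "c" / "manifest.json").read_text())
        assert manifest["seed"] == 5
        assert manifest["spec"] == [["NSR", "still", 1]]
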