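import math

import numpy as np
import pytest

from conftest import constant_fork_model, single_stage_model
from oracles import mmc_mean_queue_length, mmc_mean_wait

from trialflow.des_engine import (
    CalibrationError,
    SimulationConfig,
    calibrate_capacities,
    records_to_frame,
    replications_needed,
    run_replication,
    simulate,
)
from trialflow.process_model import BUDGET, CONTRACT


class TestDeterministicCriticalPath:
    def test_single_trial_activation_is_exact(self):
        """Constant durations, no contention: activation equals the critical path."""
        m = constant_fork_model(init=2.0, contract=10.0, budget=7.0,
                                pi=1.0, dsr=0.5, sponsor=3.0, lam=0.005)
        cfg = SimulationConfig(horizon=4000.0, warmup=0.0, replications=2)
        records, _ = run_replication(m, cfg, 5)
        done = [r for r in records if r.status == "completed"]
        assert done
        expected = 2.0 + max(10.0, 7.0) + 1.0 + 0.5 + 3.0
        for r in done:
            assert r.activation_time_total == pytest.approx(expected, abs=1e-9)
            # the faster branch waits exactly the branch-duration difference;
            # that slack is batch wait, not idle (the slower branch defines
            # the experienced service time)
            assert r.batch_wait == pytest.approx(3.0, abs=1e-9)
            assert r.idle_time_total == pytest.approx(0.0, abs=1e-9)

    def test_timestamps_nondecreasing(self):
        m = constant_fork_model(2.0, 10.0, 7.0, 1.0, 0.5, 3.0, lam=0.05)
        cfg = SimulationConfig(horizon=2000.0, warmup=0.0, replications=2)
        records, _ = run_replication(m, cfg, 1)
        for r in records:
            for q, s, e in r.visits.values():
                if not math.isnan(s):
                    assert q <= s
                if not math.isnan(e):
                    assert s <= e


class TestErlangC:
    # moderate loads (ρ ≤ 0.72) so the queue mixes well inside the horizon
    @pytest.mark.parametrize("lam,mean_service,c", [(1.8, 1.0, 3), (0.6, 1.0, 1),
                                                    (1.2, 1.0, 2)])
    def test_mean_flow_time_matches_analytic(self, lam, mean_service, c):
        """Single-stage M/M/c flow time agrees with Erlang-C within 3%."""
        m = single_stage_model(mean_service, c, lam)
        cfg = SimulationConfig(horizon=3650.0, warmup=365.0,
                               replications=10, master_seed=11)
        s = simulate(m, cfg)
        analytic = mmc_mean_wait(lam, mean_service, c) + mean_service
        assert s.means["flow_time.Stage"] == pytest.approx(analytic, rel=0.03)

    def test_queue_length_matches_analytic(self):
        lam, mean_service, c = 1.2, 1.0, 2
        m = single_stage_model(mean_service, c, lam)
        cfg = SimulationConfig(horizon=3650.0, warmup=365.0,
                               replications=10, master_seed=11)
        s = simulate(m, cfg)
        analytic = mmc_mean_queue_length(lam, mean_service, c)
        assert s.means["queue_length.Stage"] == pytest.approx(analytic, rel=0.10)


class TestAccounting:
    def test_flow_conservation_per_replication(self, ocr_model, quick_config):
        for seed in range(4):
            _, stats = run_replication(ocr_model, quick_config, seed)
            assert stats.n_arrivals == stats.n_completed + stats.n_in_process

    def test_fifo_at_capacity_one(self):
        m = single_stage_model(1.0, 1, lam=0.8)
        cfg = SimulationConfig(horizon=500.0, warmup=0.0, replications=2)
        records, _ = run_replication(m, cfg, 3)
        done = [r for r in records if r.status == "completed"]
        entries = [r.visits["Stage"][0] for r in done]
        ends = [r.visits["Stage"][2] for r in done]
        assert entries == sorted(entries)
        assert ends == sorted(ends)

    def test_nonnegative_waits_and_idle(self, ocr_model, quick_config):
        records, _ = run_replication(ocr_model, quick_config, 7)
        for r in records:
            if r.status == "completed":
                assert r.idle_time_total >= -1e-9
                assert r.batch_wait >= 0.0

    def test_event_log_frame(self, ocr_model, quick_config):
        records, _ = run_replication(ocr_model, quick_config, 7)
        df = records_to_frame(records)
        assert set(df.columns) == {"trial_id", "name", "queue_entry",
                                   "start", "end", "status"}
        assert df.trial_id.nunique() == len(records)


class TestReplications:
    def test_seed_determinism(self, ocr_model, quick_config):
        a = simulate(ocr_model, quick_config)
        b = simulate(ocr_model, quick_config)
        assert a.means == b.means
        assert a.half_widths == b.half_widths

    def test_different_seeds_differ(self, ocr_model, quick_config):
        cfg2 = SimulationConfig(horizon=quick_config.horizon,
                                warmup=quick_config.warmup,
                                replications=quick_config.replications,
                                master_seed=quick_config.master_seed + 1)
        assert simulate(ocr_model, quick_config).means["activation_time"] != \
            simulate(ocr_model, cfg2).means["activation_time"]

    def test_capacity_monotonicity_within_ci(self, ocr_model):
        """More negotiation capacity never worsens activation time (within CI)."""
        cfg = SimulationConfig(horizon=365.0, warmup=730.0, replications=10,
                               master_seed=5)
        base = simulate(ocr_model, cfg)
        bigger = ocr_model.copy()
        bigger.subprocess(CONTRACT).capacity *= 2
        bigger.subprocess(BUDGET).capacity *= 2
        fast = simulate(bigger, cfg)
        slack = base.half_widths["activation_time"] + fast.half_widths["activation_time"]
        assert fast.means["activation_time"] <= base.means["activation_time"] + slack

    def test_arrival_monotonicity_within_ci(self, ocr_model):
        cfg = SimulationConfig(horizon=365.0, warmup=730.0, replications=10,
                               master_seed=5)
        base = simulate(ocr_model, cfg)
        busier = ocr_model.copy()
        busier.arrival.scale_factor = 1.3
        slow = simulate(busier, cfg)
        slack = base.half_widths["activation_time"] + slow.half_widths["activation_time"]
        assert slow.means["activation_time"] >= base.means["activation_time"] - slack


def test_half_width_shrinks_with_replications():
    """Quadrupling replications roughly halves the 95% half-width.

    The 1/√n law holds in expectation, so the ratio is averaged over
    several independent experiments on a cheap single-stage model.
    """
    m = single_stage_model(1.0, 2, lam=0.9)
    small_sq, big_sq = [], []
    for seed in range(8):
        small = simulate(m, SimulationConfig(horizon=200, warmup=50,
                                             replications=10, master_seed=100 + seed))
        big = simulate(m, SimulationConfig(horizon=200, warmup=50,
                                           replications=40, master_seed=200 + seed))
        small_sq.append(small.half_widths["flow_time.Stage"] ** 2)
        big_sq.append(big.half_widths["flow_time.Stage"] ** 2)
    # root-mean-square ratio; expectation 2 x (t-quantile correction) ~ 2.24
    ratio = math.sqrt(np.mean(small_sq) / np.mean(big_sq))
    assert 1.6 < ratio < 2.9


class TestReplicationsNeeded:
    def test_zero_variance_pilot_returns_lower_bound(self, ocr_model, quick_config):
        pilot = simulate(ocr_model, quick_config)
        pilot.half_widths["activation_time"] = 0.0
        assert replications_needed(pilot, 0.05) == 2

    def test_matches_exhaustive_scan(self):
        """n from the closed condition equals brute-force search over n."""
        from scipy import stats as st

        cv = 0.15
        pilot_n = 10
        hw = st.t.ppf(0.975, pilot_n - 1) * cv * 100.0 / math.sqrt(pilot_n)
        pilot = _FakeSummary({"activation_time": 100.0},
                             {"activation_time": hw}, pilot_n)
        got = replications_needed(pilot, 0.05)
        feasible = [n for n in range(2, 200)
                    if st.t.ppf(0.975, n - 1) * cv / math.sqrt(n) <= 0.05]
        assert got == feasible[0]

    def test_zero_mean_rejected(self, ocr_model, quick_config):
        pilot = simulate(ocr_model, quick_config)
        pilot.means["activation_time"] = 0.0
        with pytest.raises(ValueError):
            replications_needed(pilot, 0.05)


class _FakeSummary:
    def __init__(self, means, hws, n):
        self.means, self.half_widths, self.n_replications = means, hws, n

    def __getitem__(self, k):
        return self.means[k], self.half_widths[k]


class TestCalibration:
    def test_recovers_known_capacity_on_mmc_stage(self):
        """Targeting the Erlang-C Lq of c=3 recovers capacity 3."""
        lam, mean_service = 2.4, 1.0
        target = mmc_mean_queue_length(lam, mean_service, 3)
        m = single_stage_model(mean_service, capacity=1, lam=lam)
        cfg = SimulationConfig(horizon=730.0, warmup=365.0, master_seed=2)
        cal = calibrate_capacities(m, {"Stage": target}, cfg, replications=8)
        assert cal.subprocess("Stage").capacity == 3

    def test_small_target_on_light_stage_gives_one_server(self):
        m = single_stage_model(1.0, capacity=4, lam=0.2)
        cfg = SimulationConfig(horizon=365.0, warmup=100.0, master_seed=2)
        cal = calibrate_capacities(m, {"Stage": 0.05}, cfg, replications=6)
        assert cal.subprocess("Stage").capacity == 1

    def test_baseline_untouched_and_unknown_name(self, ocr_model, quick_config):
        with pytest.raises(KeyError):
            calibrate_capacities(ocr_model, {"Nope": 1.0}, quick_config,
                                 replications=2)
        with pytest.raises(ValueError):
            calibrate_capacities(ocr_model, {CONTRACT: -1.0}, quick_config)

    def test_unstable_beyond_bound_raises(self):
        m = single_stage_model(10.0, capacity=1, lam=1.0)  # offered load 10
        with pytest.raises(CalibrationError):
            calibrate_capacities(m, {"Stage": 1.0},
                                 SimulationConfig(horizon=50, warmup=0, master_seed=0),
                                 replications=2, search_bound=5)
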