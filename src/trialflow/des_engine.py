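"""Event-calendar simulation of the activation workflow.

Each replication runs a single event loop over a heap-ordered calendar:
Poisson trial arrivals enter the source stage; every stage is a FIFO queue
with ``capacity`` identical servers; at an AND-split the trial's documents
fork and travel both branches concurrently; at an AND-join the earlier
document waits ("batching") until its sibling arrives, after which the
merged trial queues for the join stage's own service.

Measurement follows the standard warm-up / replication design: a warm-up
span is simulated but excluded, per-trial statistics cover trials arriving
inside the measurement window, and queue-length time averages integrate
over that window only.  The run is truncated at the horizon, so per-trial
means are computed over trials that *complete* within the window — the same
completion-censored accounting an operational dataset (or a fixed-length
simulation run) would produce.

Replications use independent child streams spawned from one master seed;
cross-replication means get Student-t 95% confidence half-widths.
"""

from __future__ import annotations

import heapq
import json
import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _st

from .process_model import ProcessModel

__all__ = [
    "SimulationConfig",
    "TrialRecord",
    "ReplicationStats",
    "ExperimentSummary",
    "CalibrationError",
    "run_replication",
    "simulate",
    "replications_needed",
    "calibrate_capacities",
    "records_to_frame",
    "write_event_log",
]

ENTIRE = "Entire Process"
BATCH_JOIN = "Batch Join"


@dataclass
class SimulationConfig:
    """Run-length design: measurement horizon, warm-up span, replications."""

    horizon: float = 365.0
    warmup: float = 1460.0
    replications: int = 38
    master_seed: int = 0

    def __post_init__(self):
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")
        if self.warmup < 0:
            raise ValueError("warmup must be >= 0")
        if self.replications < 2:
            raise ValueError("need at least 2 replications")


@dataclass
class TrialRecord:
    """One trial's trajectory through the workflow (times in days)."""

    trial_id: int
    arrival_time: float
    #: per sub-process: (queue_entry, service_start, service_end)
    visits: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    #: per sub-process: per-activity service durations
    services: dict[str, list[float]] = field(default_factory=dict)
    batch_release_time: float | None = None
    batch_wait: float = 0.0
    activation_time_total: float | None = None
    idle_time_total: float | None = None
    status: str = "in_process_at_horizon"

    def service_total(self, name: str) -> float:
        return sum(self.services.get(name, ()))


@dataclass
class ReplicationStats:
    """Within-replication performance measures (means over the window)."""

    flow_time: dict[str, float]          # queue + service, per sub-process + ENTIRE
    activation_mean: float
    idle_mean: float
    batch_wait_mean: float
    queue_length: dict[str, float]       # time-average waiting, + BATCH_JOIN
    n_arrivals: int
    n_completed: int
    n_in_process: int

    def measures(self) -> dict[str, float]:
        out = {
            "activation_time": self.activation_mean,
            "idle_time": self.idle_mean,
            "batch_wait": self.batch_wait_mean,
            "n_in": float(self.n_arrivals),
            "n_out": float(self.n_completed),
            "wip": float(self.n_in_process),
        }
        for k, v in self.flow_time.items():
            out[f"flow_time.{k}"] = v
        for k, v in self.queue_length.items():
            out[f"queue_length.{k}"] = v
        return out


@dataclass
class ExperimentSummary:
    """Cross-replication means with 95% Student-t confidence half-widths."""

    means: dict[str, float]
    half_widths: dict[str, float]
    n_replications: int
    master_seed: int

    def __getitem__(self, measure: str) -> tuple[float, float]:
        return self.means[measure], self.half_widths[measure]

    def ci_overlaps(self, other: "ExperimentSummary", measure: str) -> bool:
        """True iff the two 95% CIs for ``measure`` overlap."""
        lo1, hi1 = self.means[measure] - self.half_widths[measure], \
            self.means[measure] + self.half_widths[measure]
        lo2, hi2 = other.means[measure] - other.half_widths[measure], \
            other.means[measure] + other.half_widths[measure]
        return lo1 <= hi2 and lo2 <= hi1

    def to_dict(self) -> dict:
        return {
            "n_replications": self.n_replications,
            "master_seed": self.master_seed,
            "measures": {
                k: {"mean": self.means[k], "half_width_95": self.half_widths[k]}
                for k in self.means
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def table(self, observed: dict[str, float] | None = None,
              measures: list[str] | None = None) -> str:
        """Aligned text table, optionally alongside observed values."""
        keys = measures or sorted(self.means)
        rows = [("Measure", "Actual", "Simulated (95% CI)")] if observed else \
            [("Measure", "Simulated (95% CI)")]
        for k in keys:
            sim = f"{self.means[k]:.1f} ({self.half_widths[k]:.1f})"
            if observed:
                act = f"{observed[k]:.1f}" if k in observed else "-"
                rows.append((k, act, sim))
            else:
                rows.append((k, sim))
        widths = [max(len(r[i]) for r in rows) for i in range(len(rows[0]))]
        return "\n".join(
            "  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip()
            for row in rows
        )


class CalibrationError(RuntimeError):
    """Capacity calibration could not find a stable configuration."""


# ---------------------------------------------------------------------------
# single replication
# ---------------------------------------------------------------------------

_ARRIVAL = 0
_END_SERVICE = 1


class _Station:
    __slots__ = ("name", "capacity", "busy", "queue", "area", "last_t", "last_q")

    def __init__(self, name: str, capacity: int | None):
        self.name = name
        self.capacity = math.inf if capacity is None else capacity
        self.busy = 0
        self.queue = deque()  # FIFO
        self.area = 0.0
        self.last_t = 0.0
        self.last_q = 0


def _win_area(station: _Station, now: float, w0: float, w1: float) -> None:
    """Accumulate queue-length area over the overlap of [last_t, now] with the window."""
    lo = max(station.last_t, w0)
    hi = min(now, w1)
    if hi > lo:
        station.area += station.last_q * (hi - lo)
    station.last_t = now


def run_replication(model: ProcessModel, config: SimulationConfig,
                    seed) -> tuple[list[TrialRecord], ReplicationStats]:
    """Run one replication; returns per-trial records and window statistics.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    names = model.names
    # one independent substream per stochastic element, in a stable order:
    # arrivals, branch selection, then one per sub-process
    children = ss.spawn(2 + len(names))
    rng_arrival = np.random.default_rng(children[0])
    rng_branch = np.random.default_rng(children[1])
    rng_service = {n: np.random.default_rng(c) for n, c in zip(names, children[2:])}

    w0, w1 = config.warmup, config.warmup + config.horizon
    stations = {sp.name: _Station(sp.name, sp.capacity) for sp in model.subprocesses}
    join_buffer: dict[tuple[int, str], list[float]] = {}  # (trial, join) -> arrival times
    trial_taken: dict[int, int] = {}  # branches actually forked at the split
    join_pending = 0            # documents currently waiting for a sibling
    join_area = 0.0
    join_last_t = 0.0

    def join_win_area(now: float) -> None:
        nonlocal join_area, join_last_t
        lo, hi = max(join_last_t, w0), min(now, w1)
        if hi > lo:
            join_area += join_pending * (hi - lo)
        join_last_t = now

    records: dict[int, TrialRecord] = {}
    succ = model.routing
    sem = model.semantics
    preds = {n: model.predecessors(n) for n in names}
    service_paths = _service_paths(model)

    calendar: list = []
    seq = 0

    def push(t: float, kind: int, payload) -> None:
        nonlocal seq
        heapq.heappush(calendar, (t, seq, kind, payload))
        seq += 1

    def enter(name: str, trial: int, now: float) -> None:
        """Token joins station ``name``'s queue (or starts service)."""
        st = stations[name]
        rec = records[trial]
        if st.busy < st.capacity:
            rec.visits[name] = (now, now, math.nan)
            st.busy += 1
            start_service(name, trial, now)
        else:
            rec.visits[name] = (now, math.nan, math.nan)
            _win_area(st, now, w0, w1)
            st.queue.append(trial)
            st.last_q += 1

    def start_service(name: str, trial: int, now: float) -> None:
        durs = model.subprocess(name).sample_service(rng_service[name])
        rec = records[trial]
        rec.services[name] = durs
        q_entry = rec.visits[name][0]
        rec.visits[name] = (q_entry, now, now + sum(durs))
        push(now + sum(durs), _END_SERVICE, (name, trial))

    def route_onward(name: str, trial: int, now: float) -> None:
        successors = succ.get(name, [])
        if not successors:
            finish_trial(trial, now)
            return
        if sem.get(name) == "and_split":
            taken = [s for s in successors
                     if model.branch_probability.get(s, 1.0) >= 1.0
                     or rng_branch.random() < model.branch_probability.get(s, 1.0)]
            if not taken:  # every branch skipped: nothing left to do
                finish_trial(trial, now)
                return
            trial_taken[trial] = len(taken)
            for s in taken:
                deliver(s, trial, now)
        else:
            deliver(successors[0], trial, now)

    def deliver(name: str, trial: int, now: float) -> None:
        nonlocal join_pending
        if sem.get(name) == "and_join":
            key = (trial, name)
            buf = join_buffer.setdefault(key, [])
            buf.append(now)
            # documents expected = branches actually forked at the split
            # (in-degree when the fork was unconditional)
            need = trial_taken.get(trial, len(preds[name]))
            if len(buf) < need:
                join_win_area(now)
                join_pending += 1
                return
            # all sibling documents present: release the batch
            rec = records[trial]
            rec.batch_release_time = now
            rec.batch_wait = now - min(buf)
            if len(buf) > 1:
                join_win_area(now)
                join_pending -= len(buf) - 1
            del join_buffer[key]
        enter(name, trial, now)

    def finish_trial(trial: int, now: float) -> None:
        rec = records[trial]
        rec.status = "completed"
        rec.activation_time_total = now - rec.arrival_time
        va = max(sum(rec.service_total(n) for n in path if n in rec.services)
                 for path in service_paths)
        rec.idle_time_total = rec.activation_time_total - va

    # -- seed arrivals ---------------------------------------------------
    rate = model.arrival.rate
    t = 0.0
    trial_id = 0
    while True:
        t += rng_arrival.exponential(1.0 / rate)
        if t >= w1:
            break
        push(t, _ARRIVAL, trial_id)
        trial_id += 1

    # -- event loop ------------------------------------------------------
    while calendar:
        now, _, kind, payload = heapq.heappop(calendar)
        if now > w1:
            break
        if kind == _ARRIVAL:
            trial = payload
            records[trial] = TrialRecord(trial_id=trial, arrival_time=now)
            enter(model.source, trial, now)
        else:
            name, trial = payload
            st = stations[name]
            st.busy -= 1
            if st.queue:
                _win_area(st, now, w0, w1)
                nxt = st.queue.popleft()
                st.last_q -= 1
                st.busy += 1
                start_service(name, nxt, now)
            route_onward(name, trial, now)

    for st in stations.values():
        _win_area(st, w1, w0, w1)
    join_win_area(w1)

    # -- window statistics -----------------------------------------------
    window = [r for r in records.values() if w0 <= r.arrival_time < w1]
    completed = [r for r in window if r.status == "completed"]

    # flow-time means over trials completing the whole process, matching the
    # completion-censored accounting of an operational dataset truncated at
    # the horizon (incomplete trials report no final durations)
    flow: dict[str, float] = {}
    for name in names:
        times = [r.visits[name][2] - r.visits[name][0]
                 for r in completed
                 if name in r.visits and not math.isnan(r.visits[name][2])]
        flow[name] = float(np.mean(times)) if times else math.nan
    flow[ENTIRE] = float(np.mean([r.activation_time_total for r in completed])) \
        if completed else math.nan

    qlen = {n: stations[n].area / config.horizon for n in names}
    qlen[BATCH_JOIN] = join_area / config.horizon

    stats = ReplicationStats(
        flow_time=flow,
        activation_mean=flow[ENTIRE],
        idle_mean=float(np.mean([r.idle_time_total for r in completed]))
        if completed else math.nan,
        batch_wait_mean=float(np.mean([r.batch_wait for r in completed]))
        if completed else math.nan,
        queue_length=qlen,
        n_arrivals=len(window),
        n_completed=len(completed),
        n_in_process=len(window) - len(completed),
    )
    return sorted(records.values(), key=lambda r: r.trial_id), stats


def _service_paths(model: ProcessModel) -> list[list[str]]:
    """All source→sink node paths; value-added time is the max path-sum."""
    import networkx as nx

    g = model.graph()
    return [list(p) for p in nx.all_simple_paths(g, model.source, model.sink)] \
        or [[model.source]]


# ---------------------------------------------------------------------------
# replications and summaries
# ---------------------------------------------------------------------------


def simulate(model: ProcessModel, config: SimulationConfig) -> ExperimentSummary:
    """Run ``config.replications`` independent replications and summarize.

    Each replication gets an independent child stream of the master seed;
    measures are cross-replication means with 95% Student-t half-widths
    (n−1 degrees of freedom).
    """
    reps = np.random.SeedSequence(config.master_seed).spawn(config.replications)
    per_rep = [run_replication(model, config, ss)[1].measures() for ss in reps]
    keys = per_rep[0].keys()
    means, hws = {}, {}
    n = len(per_rep)
    tcrit = _st.t.ppf(0.975, n - 1)
    for k in keys:
        vals = np.array([m[k] for m in per_rep], dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            means[k], hws[k] = math.nan, math.nan
            continue
        means[k] = float(vals.mean())
        hws[k] = float(tcrit * vals.std(ddof=1) / math.sqrt(vals.size)) \
            if vals.size > 1 else math.nan
    return ExperimentSummary(means, hws, n, config.master_seed)


def replications_needed(pilot: ExperimentSummary, rel_error: float,
                        measure: str = "activation_time") -> int:
    """Smallest n with t_{n−1,0.975}·s/(√n·mean) ≤ rel_error for ``measure``.

    The pilot's cross-replication standard deviation is recovered from its
    half-width; the scan over n is exact (no normal approximation).
    """
    if not 0.0 < rel_error < 1.0:
        raise ValueError("rel_error must be in (0, 1)")
    mean, hw = pilot[measure]
    if mean == 0 or math.isnan(mean):
        raise ValueError(f"pilot mean of {measure!r} is zero; relative error undefined")
    n0 = pilot.n_replications
    s = hw * math.sqrt(n0) / _st.t.ppf(0.975, n0 - 1)
    cv = s / abs(mean)
    n = 2
    while _st.t.ppf(0.975, n - 1) * cv / math.sqrt(n) > rel_error:
        n += 1
        if n > 10**7:
            raise RuntimeError("replication count exceeds sane bound")
    return n


def calibrate_capacities(model: ProcessModel, targets: dict[str, float],
                         config: SimulationConfig | None = None,
                         replications: int = 32,
                         search_bound: int = 40) -> ProcessModel:
    """Integer capacity search against time-average queue-length targets.

    For each targeted sub-process in turn, capacities 1, 2, … are simulated
    (a short cross-replication experiment each) and the capacity minimizing
    the absolute deviation of the simulated time-average queue length from
    the target is kept.  Queue length is monotone nonincreasing in capacity,
    so the scan stops once the simulated value falls below the target and
    the deviation starts growing.  Ties go to the smaller capacity.
    """
    if any(t <= 0 for t in targets.values()):
        raise ValueError("queue-length targets must be positive")
    cfg = config or SimulationConfig()
    cal_cfg = SimulationConfig(horizon=cfg.horizon, warmup=cfg.warmup,
                               replications=replications,
                               master_seed=cfg.master_seed)
    out = model.copy()
    for name, target in targets.items():
        sp = out.subprocess(name)  # raises KeyError on unknown name
        if out.offered_load(name) >= search_bound:
            raise CalibrationError(
                f"{name}: offered load {out.offered_load(name):.1f} exceeds the "
                f"search bound {search_bound}; no stable capacity in range"
            )
        best_c, best_dev = None, math.inf
        for c in range(1, search_bound + 1):
            sp.capacity = c
            q = simulate(out, cal_cfg).means[f"queue_length.{name}"]
            dev = abs(q - target)
            if dev < best_dev:
                best_c, best_dev = c, dev
            elif q < target:
                break  # monotone: larger capacities only drift further below
        sp.capacity = best_c
    return out


# ---------------------------------------------------------------------------
# event-log export
# ---------------------------------------------------------------------------


def records_to_frame(records: list[TrialRecord]):
    """Per trial-activity event log: one row per sub-process visit."""
    import pandas as pd

    rows = []
    for r in records:
        for name, (q, s, e) in r.visits.items():
            rows.append({
                "trial_id": r.trial_id,
                "name": name,
                "queue_entry": q,
                "start": s,
                "end": e,
                "status": r.status,
            })
    return pd.DataFrame(rows, columns=["trial_id", "name", "queue_entry",
                                       "start", "end", "status"])


def write_event_log(records: list[TrialRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)
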