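"""Seeded synthetic operational datasets: timestamp logs and communication logs.

The generator emulates the statistical structure of a clinical-trial
office's operational year: Poisson trial arrivals (≈147/year by default),
per-sub-process durations drawn from the workflow model's fitted
distributions, a status mix matching the typical inclusion pattern
(78 complete : 16 missing data : 52 in process : 1 terminated, of 147),
and per-sub-process communication volumes whose out-initiation totals hit
configurable targets (contract: OCR 507 vs sponsor 346; budget: sponsor
153, PI 70 vs OCR 69+13).

Durations are sampled directly per trial with no queueing interaction —
the log emulates what the office *records* per trial, which is what the
timing and fitting analyses consume.  Interaction totals are annual counts
allocated to trials proportionally to their sub-process durations (longer
negotiations generate more messages), scattered uniformly inside the
trial's sub-process interval.

Timestamps are day offsets (reals) from study start; an optional ISO-date
rendering anchors day 0 at an arbitrary epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .process_model import (
    BUDGET, CONTRACT, ProcessModel, default_ocr_model,
)

__all__ = ["GeneratorSpec", "generate_dataset", "write_dataset",
           "fixture_paths",
           "DEFAULT_STATUS_MIX", "DEFAULT_INTERACTION_TARGETS", "ROLES"]

ROLES = ("OCR", "Sponsor", "PI", "P&L", "USF Legal", "DSR", "WIRB", "IRB")

DEFAULT_STATUS_MIX = {
    "complete": 78 / 147,
    "missing_data": 16 / 147,
    "in_process": 52 / 147,
    "terminated": 1 / 147,
}

#: annual interaction counts per (sub-process, source, target).  The
#: contract out-initiation totals (OCR 507, sponsor 346) and the budget
#: totals (sponsor 153, PI 70, OCR 69 toward the sponsor plus 13 toward the
#: PI) are the documented operational counts; the per-partner splits of the
#: contract totals and the remaining participants' small side volumes are
#: synthetic defaults chosen to keep the networks connected with
#: OCR/sponsor/PI dominant.
DEFAULT_INTERACTION_TARGETS: dict[str, dict[tuple[str, str], int]] = {
    CONTRACT: {
        ("OCR", "Sponsor"): 406,
        ("OCR", "PI"): 51,
        ("OCR", "USF Legal"): 30,
        ("OCR", "P&L"): 20,          # OCR total: 507
        ("Sponsor", "OCR"): 311,
        ("Sponsor", "USF Legal"): 35,  # sponsor total: 346
        ("PI", "OCR"): 60,
        ("USF Legal", "OCR"): 28,
        ("USF Legal", "Sponsor"): 12,
        ("P&L", "OCR"): 25,
        ("DSR", "OCR"): 15,
    },
    BUDGET: {
        ("Sponsor", "OCR"): 153,
        ("PI", "OCR"): 70,
        ("OCR", "Sponsor"): 69,
        ("OCR", "PI"): 13,
        ("P&L", "OCR"): 20,
        ("USF Legal", "OCR"): 10,
    },
}


@dataclass
class GeneratorSpec:
    """Everything the generator needs; a fixed seed gives identical output."""

    model: ProcessModel = field(default_factory=default_ocr_model)
    n_years: float = 1.0
    status_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STATUS_MIX))
    interaction_targets: dict[str, dict[tuple[str, str], int]] = field(
        default_factory=lambda: {
            sp: dict(pairs) for sp, pairs in DEFAULT_INTERACTION_TARGETS.items()
        })
    seed: int = 0

    def __post_init__(self):
        total = sum(self.status_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"status mix must sum to 1, sums to {total}")
        if self.n_years <= 0:
            raise ValueError("n_years must be > 0")
        for pair_map in self.interaction_targets.values():
            if any(count < 0 for count in pair_map.values()):
                raise ValueError("interaction volumes must be >= 0")


def fixture_paths() -> dict[str, str]:
    """Paths to the bundled synthetic fixture (seed 20, a quarter year)
    and the default model configuration.

    The CSVs are entirely synthetic — regenerate with
    ``write_dataset(GeneratorSpec(seed=20, n_years=0.25), out_dir)``.
    """
    from importlib import resources

    base = resources.files("trialflow") / "data"
    return {
        "timestamps": str(base / "fixture_timestamps.csv"),
        "communications": str(base / "fixture_communications.csv"),
        "model": str(base / "default_model.yaml"),
    }


def _topological(model: ProcessModel) -> list[str]:
    import networkx as nx

    return list(nx.topological_sort(model.graph()))


def generate_dataset(spec: GeneratorSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (timestamp log, communication log) as DataFrames.

    Timestamp log: trial_id, name, start, end, status — one row per observed
    sub-process visit.  Incompletely observed trials (missing data, in
    process, terminated) carry correspondingly truncated or punctured rows.

    Communication log: timestamp, source, target, subprocess, trial_id.
    """
    rng = np.random.default_rng(spec.seed)
    model = spec.model
    horizon = spec.n_years * 365.0
    order = _topological(model)
    preds = {n: model.predecessors(n) for n in order}

    # -- arrivals --------------------------------------------------------
    arrivals = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / model.arrival.rate)
        if t >= horizon:
            break
        arrivals.append(t)

    statuses = list(spec.status_mix)
    probs = np.array([spec.status_mix[s] for s in statuses])

    ts_rows = []
    trial_spans: dict[int, dict[str, tuple[float, float]]] = {}
    trial_status: dict[int, str] = {}
    for trial_id, arr in enumerate(arrivals):
        # unconditional traversal unless a branch-skip probability says otherwise
        visited = {}
        for name in order:
            p = model.branch_probability.get(name, 1.0)
            if preds[name] and not any(q in visited for q in preds[name]):
                continue
            if p < 1.0 and rng.random() >= p:
                continue
            start = arr if not preds[name] else max(
                visited[q][1] for q in preds[name] if q in visited)
            dur = sum(model.subprocess(name).sample_service(rng))
            visited[name] = (start, start + dur)

        status = statuses[rng.choice(len(statuses), p=probs)]
        trial_status[trial_id] = status
        trial_spans[trial_id] = visited

        items = sorted(visited.items(), key=lambda kv: (kv[1][0], kv[0]))
        if status == "missing_data" and len(items) > 1:
            drop = rng.integers(len(items))
            items = [it for i, it in enumerate(items) if i != drop]
        elif status in ("in_process", "terminated") and len(items) > 1:
            keep = int(rng.integers(1, len(items)))
            items = items[:keep]
        for name, (start, end) in items:
            ts_rows.append({"trial_id": trial_id, "name": name,
                            "start": start, "end": end, "status": status})

    timestamps = pd.DataFrame(
        ts_rows, columns=["trial_id", "name", "start", "end", "status"])

    # -- communications --------------------------------------------------
    comm_rows = []
    complete_ids = [i for i, s in trial_status.items() if s == "complete"]
    for subproc, pairs in spec.interaction_targets.items():
        carriers = [i for i in complete_ids if subproc in trial_spans[i]]
        if not carriers:
            continue
        durs = np.array([trial_spans[i][subproc][1] - trial_spans[i][subproc][0]
                         for i in carriers])
        weights = durs / durs.sum() if durs.sum() > 0 else np.full(len(durs), 1 / len(durs))
        for (source, target), annual_count in pairs.items():
            total = int(round(annual_count * spec.n_years))
            if total == 0:
                continue
            # exact total, allocated across trials by negotiation length
            per_trial = rng.multinomial(total, weights)
            for i, count in zip(carriers, per_trial):
                if count == 0:
                    continue
                lo, hi = trial_spans[i][subproc]
                for tm in rng.uniform(lo, hi, count):
                    comm_rows.append({"timestamp": tm, "source": source,
                                      "target": target,
                                      "subprocess": subproc, "trial_id": i})

    communications = pd.DataFrame(
        comm_rows, columns=["timestamp", "source", "target", "subprocess", "trial_id"])
    if not communications.empty:
        communications = communications.sort_values(
            ["subprocess", "source", "timestamp"], kind="stable").reset_index(drop=True)
    return timestamps, communications


def write_dataset(spec: GeneratorSpec, out_dir, iso_dates: bool = False,
                  epoch: str = "2011-07-01") -> dict[str, str]:
    """Write timestamps.csv and communications.csv under ``out_dir``.

    With ``iso_dates`` the day offsets are rendered as ISO-8601 timestamps
    anchored at ``epoch`` (the anchor is irrelevant to every statistic).
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    ts, comm = generate_dataset(spec)
    if iso_dates:
        anchor = pd.Timestamp(epoch)
        for col in ("start", "end"):
            ts[col] = anchor + pd.to_timedelta(ts[col], unit="D")
        if not comm.empty:
            comm["timestamp"] = anchor + pd.to_timedelta(comm["timestamp"], unit="D")
    paths = {
        "timestamps": os.path.join(out_dir, "timestamps.csv"),
        "communications": os.path.join(out_dir, "communications.csv"),
    }
    ts.to_csv(paths["timestamps"], index=False)
    comm.to_csv(paths["communications"], index=False)
    return paths
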