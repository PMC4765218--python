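"""The activation-workflow model: sub-processes, routing, capacities, arrivals.

A :class:`ProcessModel` is a directed acyclic graph of named sub-processes.
Each node is served by a finite (or unbounded) pool of identical servers with
a FIFO queue; node semantics are ``sequence`` (one successor), ``and_split``
(on completion the trial's paperwork forks to every successor, e.g. contract
and budget documents travelling in parallel) or ``and_join`` (service cannot
start until every forked document of the trial has arrived — the
"batching" synchronization).  Trials arrive in a Poisson stream.

The bundled default encodes an academic clinical-trial office's workflow:
Initial Preparation (four serial activities), a parallel Contract/Budget
negotiation pair re-joined at PI Approval, then DSR and Sponsor approvals.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import networkx as nx
import yaml

from .stat_distributions import DurationDistribution

__all__ = [
    "DurationDistribution",
    "SubProcess",
    "ArrivalProcess",
    "ProcessModel",
    "ModelValidationError",
    "UnknownFamilyError",
    "CyclicRoutingError",
    "MissingEndpointError",
    "load_model",
    "write_model",
    "model_to_dict",
    "model_from_dict",
    "default_ocr_model",
    "INITIAL_PREP",
    "CONTRACT",
    "BUDGET",
    "PI_APPROVAL",
    "DSR_APPROVAL",
    "SPONSOR_APPROVAL",
]

# canonical sub-process names of the default workflow
INITIAL_PREP = "Initial Preparation"
CONTRACT = "Contract Negotiation"
BUDGET = "Budget Negotiation"
PI_APPROVAL = "PI Approval"
DSR_APPROVAL = "DSR Approval"
SPONSOR_APPROVAL = "Sponsor Approval"


class ModelValidationError(ValueError):
    """A ProcessModel invariant is violated."""


class UnknownFamilyError(ModelValidationError):
    """A configuration references an unknown distribution family."""


class CyclicRoutingError(ModelValidationError):
    """The routing graph contains a cycle."""


class MissingEndpointError(ModelValidationError):
    """Source or sink is missing / not unique."""


@dataclass
class SubProcess:
    """One stage of the workflow.

    ``duration`` is either a single :class:`DurationDistribution` or an
    ordered list of ``(activity_name, DurationDistribution)`` executed in
    series while the trial holds one server.  ``capacity`` is the number of
    trials the stage can work on concurrently (``None`` = unbounded).
    """

    name: str
    duration: DurationDistribution | list[tuple[str, DurationDistribution]]
    capacity: int | None = None

    def __post_init__(self):
        if not self.name:
            raise ModelValidationError("sub-process name must be non-empty")
        if isinstance(self.duration, list):
            if not self.duration:
                raise ModelValidationError(f"{self.name}: activity list must be non-empty")
            self.duration = [(str(a), d) for a, d in self.duration]
        if self.capacity is not None:
            if int(self.capacity) != self.capacity or self.capacity < 1:
                raise ModelValidationError(
                    f"{self.name}: capacity must be a positive integer or unbounded"
                )
            self.capacity = int(self.capacity)

    @property
    def activities(self) -> list[tuple[str, DurationDistribution]]:
        """The serial activity breakdown (a single pseudo-activity if atomic)."""
        if isinstance(self.duration, list):
            return list(self.duration)
        return [(self.name, self.duration)]

    @property
    def service_mean(self) -> float:
        """Theoretical mean service time in days (sum over serial activities)."""
        return sum(d.mean for _, d in self.activities)

    def sample_service(self, rng) -> list[float]:
        """One service realisation: a duration per serial activity."""
        return [float(d.sample(rng)) for _, d in self.activities]


@dataclass
class ArrivalProcess:
    """Poisson arrivals of trials, in trials per calendar day."""

    base_rate: float
    scale_factor: float = 1.0

    def __post_init__(self):
        if self.base_rate <= 0:
            raise ModelValidationError("arrival base_rate must be > 0")
        if self.scale_factor <= 0:
            raise ModelValidationError("arrival scale_factor must be > 0")

    @property
    def rate(self) -> float:
        return self.base_rate * self.scale_factor


SEMANTICS = ("sequence", "and_split", "and_join")


@dataclass
class ProcessModel:
    """Validated workflow: sub-processes + routing graph + arrival process.

    ``routing`` maps each sub-process name to its successors; ``semantics``
    labels nodes ``sequence`` / ``and_split`` / ``and_join``.
    ``branch_probability`` optionally lets a split successor be skipped
    (probability of traversal, default 1.0 — an unconditional fork).
    """

    subprocesses: list[SubProcess]
    routing: dict[str, list[str]]
    semantics: dict[str, str]
    arrival: ArrivalProcess
    source: str = ""
    sink: str = ""
    branch_probability: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- access helpers --------------------------------------------------

    def subprocess(self, name: str) -> SubProcess:
        for sp in self.subprocesses:
            if sp.name == name:
                return sp
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [sp.name for sp in self.subprocesses]

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.names)
        for u, succs in self.routing.items():
            for v in succs:
                g.add_edge(u, v)
        return g

    def predecessors(self, name: str) -> list[str]:
        return [u for u, succs in self.routing.items() if name in succs]

    def copy(self) -> "ProcessModel":
        return copy.deepcopy(self)

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        names = self.names
        if len(set(names)) != len(names):
            raise ModelValidationError("sub-process names must be unique")
        name_set = set(names)
        for u, succs in self.routing.items():
            for node in [u, *succs]:
                if node not in name_set:
                    raise ModelValidationError(f"routing references unknown sub-process {node!r}")
        for n, sem in self.semantics.items():
            if sem not in SEMANTICS:
                raise ModelValidationError(f"{n}: unknown node semantics {sem!r}")
        for n in names:
            self.semantics.setdefault(n, "sequence")

        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise CyclicRoutingError("routing graph contains a cycle")

        sources = [n for n in g.nodes if g.in_degree(n) == 0]
        sinks = [n for n in g.nodes if g.out_degree(n) == 0]
        if len(sources) != 1 or len(sinks) != 1:
            raise MissingEndpointError(
                f"model must have exactly one source and one sink, found "
                f"sources={sources}, sinks={sinks}"
            )
        if not self.source:
            self.source = sources[0]
        if not self.sink:
            self.sink = sinks[0]
        if self.source != sources[0] or self.sink != sinks[0]:
            raise MissingEndpointError(
                f"declared source/sink ({self.source!r}/{self.sink!r}) disagree "
                f"with the routing graph ({sources[0]!r}/{sinks[0]!r})"
            )

        reachable = nx.descendants(g, self.source) | {self.source}
        if reachable != set(g.nodes):
            raise ModelValidationError(
                f"unreachable from source: {sorted(set(g.nodes) - reachable)}"
            )
        coreach = nx.ancestors(g, self.sink) | {self.sink}
        if coreach != set(g.nodes):
            raise ModelValidationError(
                f"cannot reach sink from: {sorted(set(g.nodes) - coreach)}"
            )

        for n in names:
            sem = self.semantics[n]
            if sem == "and_split" and g.out_degree(n) < 2:
                raise ModelValidationError(f"and_split node {n!r} needs >= 2 successors")
            if sem == "and_join" and g.in_degree(n) < 2:
                raise ModelValidationError(f"and_join node {n!r} needs >= 2 predecessors")

        for n, p in self.branch_probability.items():
            if n not in name_set:
                raise ModelValidationError(f"branch_probability references unknown node {n!r}")
            if not 0.0 <= p <= 1.0:
                raise ModelValidationError(f"branch_probability[{n!r}] must be in [0, 1]")

    # -- offered load ----------------------------------------------------

    def offered_load(self, name: str) -> float:
        """λ·E[S] at a stage — mean number of busy servers if never blocked."""
        p = self.branch_probability.get(name, 1.0)
        return self.arrival.rate * p * self.subprocess(name).service_mean


# ---------------------------------------------------------------------------
# configuration (YAML) round-trip
# ---------------------------------------------------------------------------


def _dist_to_cfg(d: DurationDistribution) -> dict:
    return {"family": d.family, "params": list(d.params)}


def _dist_from_cfg(cfg: dict) -> DurationDistribution:
    try:
        fam = cfg["family"]
    except (TypeError, KeyError):
        raise ModelValidationError(f"malformed distribution config: {cfg!r}") from None
    try:
        return DurationDistribution(fam, cfg.get("params", ()))
    except ValueError as exc:
        if "unknown distribution family" in str(exc):
            raise UnknownFamilyError(str(exc)) from None
        raise ModelValidationError(str(exc)) from None


def model_to_dict(model: ProcessModel) -> dict:
    subs = []
    for sp in model.subprocesses:
        entry: dict = {"name": sp.name}
        if isinstance(sp.duration, list):
            entry["activities"] = [
                {"name": a, **_dist_to_cfg(d)} for a, d in sp.duration
            ]
        else:
            entry["duration"] = _dist_to_cfg(sp.duration)
        entry["capacity"] = sp.capacity
        subs.append(entry)
    return {
        "subprocesses": subs,
        "routing": {u: list(v) for u, v in model.routing.items()},
        "semantics": dict(model.semantics),
        "arrival": {
            "base_rate": model.arrival.base_rate,
            "scale_factor": model.arrival.scale_factor,
        },
        "source": model.source,
        "sink": model.sink,
        "branch_probability": dict(model.branch_probability),
    }


def model_from_dict(cfg: dict) -> ProcessModel:
    try:
        sub_cfgs = cfg["subprocesses"]
        arrival_cfg = cfg["arrival"]
    except (TypeError, KeyError) as exc:
        raise ModelValidationError(f"configuration missing section: {exc}") from None
    subs = []
    for entry in sub_cfgs:
        if "activities" in entry:
            duration = [(a["name"], _dist_from_cfg(a)) for a in entry["activities"]]
        else:
            duration = _dist_from_cfg(entry["duration"])
        subs.append(SubProcess(entry["name"], duration, entry.get("capacity")))
    return ProcessModel(
        subprocesses=subs,
        routing={u: list(v) for u, v in cfg.get("routing", {}).items()},
        semantics=dict(cfg.get("semantics", {})),
        arrival=ArrivalProcess(**arrival_cfg),
        source=cfg.get("source", ""),
        sink=cfg.get("sink", ""),
        branch_probability=dict(cfg.get("branch_probability", {})),
    )


def load_model(source) -> ProcessModel:
    """Load and validate a ProcessModel from a YAML path/stream or a dict."""
    if isinstance(source, dict):
        return model_from_dict(source)
    if hasattr(source, "read"):
        return model_from_dict(yaml.safe_load(source))
    with open(source) as fh:
        return model_from_dict(yaml.safe_load(fh))


def write_model(model: ProcessModel, path) -> None:
    """Write the model as YAML; ``load_model`` reproduces it exactly."""
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# the bundled default workflow
# ---------------------------------------------------------------------------


def default_ocr_model() -> ProcessModel:
    """Baseline clinical-trial-activation workflow of an academic office.

    Service-time distributions (calendar days) are the fitted/estimated
    values for the six stages; arrivals are Poisson at 147 trials/year.
    Contract and Budget Negotiation run in parallel between an AND-split
    after Initial Preparation and an AND-join at PI Approval ("batching").

    Negotiation capacities (12 and 10 concurrent trials) are the integers
    found by :func:`trialflow.des_engine.calibrate_capacities` against the
    baseline time-average queue-length targets of 18.5 (contract) and 15.2
    (budget) trials; the budget target sits between the achievable values
    at 10 and 11 servers and the calibration resolves to 10 (the modal
    argmin across seeds).  The remaining stages get ample, non-binding
    capacity.
    """
    subs = [
        SubProcess(
            INITIAL_PREP,
            [
                ("OCR sends documents", DurationDistribution("uniform", (0.5, 1.0))),
                ("P&L reviews", DurationDistribution("triangular", (1.0, 8.0, 21.0))),
                ("PI prepares documents", DurationDistribution("triangular", (1.0, 2.0, 3.0))),
                ("P&L reviews (2)", DurationDistribution("uniform", (0.5, 1.0))),
            ],
            capacity=8,
        ),
        SubProcess(CONTRACT, DurationDistribution("exponential", (28.5,)), capacity=12),
        SubProcess(BUDGET, DurationDistribution("exponential", (25.0,)), capacity=10),
        SubProcess(PI_APPROVAL, DurationDistribution("lognormal", (5.0, 8.3)), capacity=4),
        SubProcess(DSR_APPROVAL, DurationDistribution("lognormal", (2.5, 2.8)), capacity=3),
        SubProcess(SPONSOR_APPROVAL, DurationDistribution("lognormal", (6.5, 15.9)), capacity=6),
    ]
    routing = {
        INITIAL_PREP: [CONTRACT, BUDGET],
        CONTRACT: [PI_APPROVAL],
        BUDGET: [PI_APPROVAL],
        PI_APPROVAL: [DSR_APPROVAL],
        DSR_APPROVAL: [SPONSOR_APPROVAL],
        SPONSOR_APPROVAL: [],
    }
    semantics = {
        INITIAL_PREP: "and_split",
        PI_APPROVAL: "and_join",
    }
    return ProcessModel(
        subprocesses=subs,
        routing=routing,
        semantics=semantics,
        arrival=ArrivalProcess(base_rate=147.0 / 365.0),
        source=INITIAL_PREP,
        sink=SPONSOR_APPROVAL,
    )
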