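import numpy as np
import pytest

from trialflow import SimulationConfig, default_ocr_model
from trialflow.process_model import (
    ArrivalProcess, DurationDistribution, ProcessModel, SubProcess,
)


@pytest.fixture
def ocr_model():
    return default_ocr_model()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quick_config():
    """Small replication design for fast experiments in unit tests."""
    return SimulationConfig(horizon=365.0, warmup=365.0, replications=6, master_seed=3)


def single_stage_model(mean_service: float, capacity: int | None,
                       lam: float) -> ProcessModel:
    """An M/M/c queue expressed as a one-node workflow."""
    return ProcessModel(
        subprocesses=[SubProcess("Stage", DurationDistribution("exponential", (mean_service,)),
                                 capacity=capacity)],
        routing={"Stage": []},
        semantics={},
        arrival=ArrivalProcess(base_rate=lam),
    )


def constant_fork_model(init: float, contract: float, budget: float,
                        pi: float, dsr: float, sponsor: float,
                        lam: float = 0.01) -> ProcessModel:
    """The default topology with constant durations and unbounded capacity."""
    mk = lambda c: DurationDistribution("constant", (c,))
    subs = [
        SubProcess("Init", mk(init)),
        SubProcess("Contract", mk(contract)),
        SubProcess("Budget", mk(budget)),
        SubProcess("PI", mk(pi)),
        SubProcess("DSR", mk(dsr)),
        SubProcess("Sponsor", mk(sponsor)),
    ]
    routing = {"Init": ["Contract", "Budget"], "Contract": ["PI"], "Budget": ["PI"],
               "PI": ["DSR"], "DSR": ["Sponsor"], "Sponsor": []}
    return ProcessModel(subprocesses=subs, routing=routing,
                        semantics={"Init": "and_split", "PI": "and_join"},
                        arrival=ArrivalProcess(base_rate=lam))
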