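# trialflow

Process analytics for the *administrative activation* of industry-sponsored
clinical trials — the paperwork pipeline that runs from a study protocol
arriving at an academic Office of Clinical Research (OCR) to the trial being
open for patient enrollment.  The toolkit is written for healthcare
operations analysts and clinical-research administrators who want to locate
bottlenecks in that pipeline and evaluate improvement scenarios *before*
committing staff to them.

It combines three classical tools in one workflow:

1. **Value-stream timing analytics** over activity-timestamp logs —
   per-sub-process duration statistics (mean, median, SD, IQR), inclusion
   filtering by trial status, and the equal-variance two-sample *t* test.
2. **Social-network analysis** of participant communication logs — directed
   weighted networks with degree, closeness, betweenness, and Bonacich
   power centralities, identifying who must be involved in an improvement
   effort.
3. **Discrete-event simulation** of the activation workflow — a fork–join
   queueing network with finite-capacity FIFO stages, batch
   synchronization, warm-up truncation, and replication analysis with
   Student-*t* confidence intervals, plus a scenario laboratory for
   capacity and variability experiments.

## The model

The default workflow is a six-stage directed acyclic graph:

```
Initial Preparation ──┬─ Contract Negotiation ─┐
     (AND-split)      └─ Budget Negotiation  ──┴─ [batch] → PI Approval
                                                    → DSR Approval → Sponsor Approval
```

Trials arrive in a Poisson stream at rate λ = 147/365 per calendar day.
Each stage *i* is an M/G/c queue: `c_i` identical servers (the number of
trials the stage can actively work on), FIFO discipline, and a fitted
service-time distribution `S_i` in calendar days — e.g. Contract
Negotiation ~ Exponential(28.5), PI Approval ~ Lognormal(5.0, 8.3) (mean
and SD of the variate).  After Initial Preparation the trial's contract and
budget documents travel both branches concurrently; at the AND-join the
earlier-finishing document waits ("batching") until its sibling arrives.
Per completed trial the simulator records

* **activation time** `T` = last approval − protocol receipt,
* **value-added time** `V` = the maximum over source→sink paths of the
  trial's own service times (the parallel section contributes the slower
  branch),
* **idle time** `T − V`, and the **batch wait** = |contract finish −
  budget finish|.

Experiments run `R` independent replications (default 38) of a 1-year
measurement window preceded by a 4-year warm-up; every reported measure is
a cross-replication mean with a 95% Student-*t* half-width.  Negotiation
capacities are calibrated by integer search against time-average
queue-length targets (18.5 and 15.2 waiting trials), which yields 12
contract and 10 budget servers.

Duration distributions are selected from candidate families
(uniform/triangular/exponential/lognormal) by method-of-moments estimation
and a minimum sum-of-squared-errors criterion on a Sturges-binned
histogram.  The Bonacich power index is `c(β) = α(I − βA)⁻¹A·1` on the
symmetrized binary adjacency with Σc² = n and β < 0 by default, so a
participant scores high when its neighbors are otherwise unconnected.

## Worked example

```python
from trialflow import default_ocr_model, simulate, SimulationConfig

summary = simulate(default_ocr_model(), SimulationConfig(replications=38, master_seed=1))
print(summary.table(measures=["flow_time.Contract Negotiation",
                              "flow_time.Entire Process",
                              "idle_time", "batch_wait", "n_in", "n_out"]))
```

prints

```
Measure                         Simulated (95% CI)
flow_time.Contract Negotiation  60.3 (11.6)
flow_time.Entire Process        122.7 (15.9)
idle_time                       59.8 (16.2)
batch_wait                      45.4 (11.1)
n_in                            150.1 (3.0)
n_out                           96.3 (6.7)
```

— with the calibrated capacities the negotiation stages run near
saturation: a trial spends 60.3 days in contract negotiation
(queue + service) and 122.7 days end to end on average, 59.8 of which are
idle; ~150 trials arrive per year and ~96 complete within the window.

The same pipeline from the shell, using the bundled synthetic fixture
generator:

```bash
trialflow generate --years 1 --seed 7 --out-dir data/
trialflow vsm --input data/timestamps.csv --out stats.csv
trialflow sna --input data/communications.csv --subprocess "Contract Negotiation"
trialflow simulate --reps 38 --seed 1 --out sim.json
trialflow scenarios --reps 38 --seed 1 --out scenarios.csv
```

`sna` reports, per participant, in/out degree, betweenness, in/out
(harmonic) closeness and Bonacich power; on the contract network the OCR
dominates every measure (e.g. out-degree 4, betweenness 14, power 2.40),
mirroring its coordinating role.

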