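# Methods

This note documents the models, estimators, and numerical choices behind
trialflow, and states precisely what the bundled defaults do and do not
reproduce.

## Workflow model

The activation process is a directed acyclic graph of sub-processes with
three node semantics: `sequence` (one successor), `and_split` (on service
completion the trial's documents fork to every successor) and `and_join`
(service starts only after every forked document of the trial has
arrived).  Validation enforces a unique source and sink, full
reachability, acyclicity, and in/out-degree constraints on split/join
nodes.  An optional per-branch traversal probability (default 1.0, i.e. an
unconditional fork) lets a split successor be skipped; the join then waits
only for the branches actually taken.

Each sub-process is served by `capacity` identical servers with a FIFO
queue; `capacity = None` means unbounded.  A sub-process may carry a
single service-time distribution or an ordered list of serial activities;
a trial holds one server for the whole serial sequence.  Time is
continuous calendar days, 24/7 — the reference data are reported in
calendar days, so no shift calendar is modelled.

### Default parameterization

| Stage | Service distribution (days) | Capacity |
|---|---|---|
| Initial Preparation | Uniform(0.5,1) + Triangular(1,8,21) + Triangular(1,2,3) + Uniform(0.5,1), in series | 8 |
| Contract Negotiation | Exponential(28.5) | 12 (calibrated) |
| Budget Negotiation | Exponential(25.0) | 10 (calibrated) |
| PI Approval | Lognormal(5.0, 8.3) | 4 |
| DSR Approval | Lognormal(2.5, 2.8) | 3 |
| Sponsor Approval | Lognormal(6.5, 15.9) | 6 |

Arrivals are Poisson at 147/365 trials/day (the observed 147 trials/year;
the rounder "14 per month" figure would be 168/year and is treated as a
rounded statement).  Lognormal parameters are the mean and SD of the
variate itself, converted internally via σ² = ln(1+(sd/mean)²),
μ = ln(mean) − σ²/2.  Non-negotiation capacities are ample by
construction (offered load λ·E[S] well below capacity) so that only the
negotiation stages are binding, matching the observed bottleneck
structure; they are deliberately finite so capacity scenarios can touch
them.

The four Initial Preparation activity means sum to 13.5 days; the
reference validation table lists 10.9 days for this stage (its granular
activity graph is not public and may overlap activities).  The series form
is kept and the ~2.6-day gap is accepted rather than re-fitted.

## Simulation and measurement

A replication is one pass of a heap-ordered event calendar over
[0, warm-up + horizon] (defaults: 1460 + 365 days).  Statistics cover
trials **arriving inside the measurement window**; queue-length time
averages integrate over the window only.  The run truncates at the
horizon, so per-trial means (activation, idle, batch wait, per-stage flow
times) are computed over trials that **complete** within the window.  This
completion-censored accounting is intentional: it is what an operational
dataset truncated at an observation horizon produces, and it is the only
accounting under which the reference study's own simulated stage means can
fall below their service means (e.g. sponsor approval 5.2 < E[S] = 6.5).
Censoring biases long-duration measures downward; the bias grows with
congestion.

Definitions per completed trial:

* activation time `T` = sink service end − arrival;
* value-added time `V` = max over source→sink paths of the sum of the
  trial's own service durations on that path (the parallel section thus
  contributes the slower branch's services);
* idle time = `T − V` (≥ 0); the faster branch's synchronization slack is
  *not* idle — it is recorded separately as batch wait = |contract
  completion − budget completion|.

Counts (`n_in`, `n_out`, WIP) partition window arrivals exactly, giving
per-replication flow conservation by construction (and by test).

Randomness: one master seed spawns one `SeedSequence` child per
replication; within a replication, further independent substreams drive
arrivals, branch selection, and each stage's service times.  Keeping
substreams keyed by stage makes runs with modified capacities largely
common-random-number aligned across scenarios.  No attempt is made to
reproduce any other tool's stream numbering bit-for-bit.

`simulate` aggregates R replications into cross-replication means with
95% Student-t half-widths (R−1 df).  `replications_needed` returns the
smallest n with t₀.₉₇₅,ₙ₋₁·s/(√n·mean) ≤ a target relative error, using
the pilot's cross-replication s.

### Capacity calibration

`calibrate_capacities` performs, per targeted stage, an integer scan
c = 1, 2, … minimizing |simulated time-average queue length − target|,
simulating a short cross-replication experiment per candidate (32
replications by default — near criticality the window queue average has a
cross-replication CV near 1, and fewer replications make the argmin
seed-unstable).  The scan stops once the simulated queue falls below the
target and the deviation grows (queue length is monotone in capacity);
ties go to the smaller capacity.  Against the default targets
(18.5 / 15.2 waiting trials) the contract stage resolves stably to 12
servers; the budget target falls between the achievable window averages
at 10 servers (ρ ≈ 1.007, queue ≈ 19–27) and 11 servers (queue ≈ 5), and
the argmin is 10 on most seeds — the frozen default.  The baseline is
therefore *deliberately* operated at the edge of stability; that is what
the queue-length targets imply.

## Scenario laboratory

Scenarios are declarative transforms of a baseline model: an arrival-rate
multiplier, per-stage capacity multipliers (applied to the calibrated
integers, rounded half-up, floor 1), and mean-preserving variability swaps
(default: Exponential(μ) → Triangular(0.5μ, μ, 1.5μ), which keeps the mean
exactly and cuts the variance from μ² to μ²/24).  `run_suite` simulates
baseline and scenarios under one replication design and flags a difference
as significant when the two 95% CIs do not overlap.  The bundled suite
contains the five standard studies: arrivals ×16/14, doubled negotiation
capacity, doubled arrivals, doubled non-bottleneck capacity, and reduced
negotiation variability.

## Distribution fitting

`fit_distribution` estimates each candidate family by the method of
moments — exponential: sample mean; uniform: sample min/max; triangular:
sample min/max with the mode at the peak histogram bin midpoint;
lognormal: moments of log-durations (the raw sample SD of a variate with
CV ≈ 1.7 is too unstable), converted back to the (mean, sd) convention —
and scores each candidate by the sum of squared errors between the
relative-frequency histogram (Sturges' rule bins) and the candidate's bin
probabilities (CDF increments).  Bin probabilities, not point densities,
are compared: a strongly skewed density varies by orders of magnitude
inside a coarse first bin, and midpoint evaluation would systematically
favour flatter families.  SSE values are binning-dependent and are only
meaningful as an argmin.  Ties within 10⁻⁶ go to the family with fewer
parameters.  Zero-variance samples return a degenerate constant fit
flagged as such; fitting requires n ≥ 10 nonnegative durations.

## Timing analytics

`duration_stats` reports n, mean, median, SD, Q1, Q3 and IQR per
sub-process and for the entire process (per-trial last end − first start),
over fully-observed trials only; `filter_included_trials` tallies
exclusions by status (missing data / in process / terminated).  Quartiles
use linear interpolation (numpy default, "type 7"); with a single
observation the SD is reported as 0 with n = 1 flagging it.  The
equal-variance two-sample t test is the pooled-variance statistic with
nₓ+n_y−2 df (zero pooled variance raises unless the samples are identical
constants, which returns t = 0, p = 1).

## Interaction networks

Communication records aggregate into a directed graph with integer tie
weights (interaction counts); self-loops are dropped by default.
Geodesic-based measures (closeness, betweenness) run on the binarized
digraph; weights feed only the weighted degree variant.  Closeness is
harmonic by default — Σ 1/d with unreachable pairs contributing 0 —
because empirical communication networks are rarely strongly connected;
classic Freeman closeness is available as an option.  Betweenness is
directed and unnormalized (Σ σ_st(v)/σ_st).  The Bonacich power index is
computed on the symmetrized binary adjacency by a direct linear solve of
(I − βA)x = A·1, rescaled so Σx² = n; β defaults to −0.75/λ_max (negative:
power accrues to nodes whose neighbors are otherwise unconnected) and
must satisfy |β| < 1/λ_max.

## Synthetic data generator

The generator emulates one year of office operations: Poisson arrivals,
per-trial stage durations drawn independently from the model's service
distributions (no queueing — the log emulates recorded durations, which is
what the timing and fitting analyses consume), a multinomial status mix of
78:16:52:1 (complete : missing data : in process : terminated, of 147),
truncated or punctured timestamp rows for incompletely observed trials,
and communication events.  Interaction counts are exact annual totals per
(sub-process, source, target) pair — contract: OCR 507 vs sponsor 346
out-initiations; budget: sponsor 153 and PI 70 vs OCR 69 + 13 — allocated
across complete trials by a multinomial weighted by each trial's
negotiation duration (longer negotiations generate more messages; a
modelling convenience) and scattered uniformly inside the stage interval.
Pair splits beyond the documented totals, and the minor participants' side
volumes, are synthetic defaults chosen to keep the networks connected.
Timestamps are real-valued day offsets; an ISO-date rendering anchored at
an arbitrary epoch is optional.  A fixed seed yields byte-identical files.
What the generator does **not** emulate: queueing correlation between
stage durations and workload, seasonal arrival patterns, message content,
and participant rosters beyond the eight named roles — so passing
round-trip tests demonstrates estimator correctness, not realism of any
particular office.

## Fidelity to the reference study

The defaults encode a published operational study of trial activation, and
the test suite checks the simulated baseline against that study's printed
validation and scenario values.  Three of those printed quantities are
mutually inconsistent with *any* fixed-capacity FIFO queueing model, so
part of the comparison fails honestly:

* **Queue lengths vs flow times.** At λ ≈ 0.403 trials/day, Little's law
  makes a time-average contract queue of 18.5 waiting trials equivalent to
  a mean wait of ≈ 46 days; the printed contract flow time of 51.6 days
  implies ≈ 23 days.  Calibrating capacities to the queue-length targets
  (as this package does) therefore produces a slower baseline
  (entire process ≈ 123 days vs 82 printed).
* **Capacity gains vs saturation headroom.** A −23-day gain from doubling
  negotiation capacity requires ≈ 20+ days of baseline negotiation wait,
  while a *finite* activation time under doubled arrivals requires
  capacity ≥ twice the offered load — which would eliminate baseline
  waiting.  No fixed capacity satisfies both; under the calibrated
  baseline, doubled arrivals saturate the network and no post-warm-up
  trial completes within the window (reported as null, not extrapolated).
* **Batch wait.** With independent branch durations Exponential(28.5) and
  Exponential(25), the synchronization wait is bounded below by
  E|S_c − S_b| ≈ 26.9 days even with zero queueing; the printed 14.2 days
  is unreachable without cross-branch correlation (plausibly an artifact
  of the original tool drawing every stage from one shared random-number
  stream, a coupling deliberately not reproduced here).

Qualitative findings are reproduced: the negotiation stages are the
bottleneck; balanced extra negotiation capacity collapses queues and idle
time while unbalanced or non-bottleneck capacity changes nothing
significant; reduced negotiation variability shortens batching
significantly without improving activation time.  The study's observed
duration table, centrality values, and post-hoc p-values derive from a
non-public dataset and are out of scope.

## Problem sizes

Default experiments (38 replications × 5 simulated years at ~147
arrivals/year) run in ~2 s each on one CPU; full capacity calibration
takes ~2 minutes; the whole test suite, including the acceptance
comparisons, under a minute.  Oracle checks use moderate-load M/M/c
instances (ρ ≤ 0.72) because near-critical queues mix too slowly for tight
analytic comparisons at these horizons — verified against an independent
simulator during development.
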