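# Methods

## Model structure

The simulator couples three layers:

1. **Arrival and allocation.** Patient arrivals are a renewal process with
   Exp(1 week) interarrivals; exactly 1040 patients are generated per
   replication. Donor arrivals (traditional paradigm only) are generated
   over the full 1040-week window as a mixed-exponential renewal process:
   each interarrival is Exp(m) with a fresh m ~ Uniform(1, 5) weeks. The
   allograft queue is first-come-first-served with infinite capacity; a
   donor finding the queue empty is discarded (menisci are patient-matched
   at arrival, not banked), and a patient who reaches 104 waiting weeks is
   removed to TKA at exactly that instant. When a donor arrives at a
   patient's exact timeout instant, the timeout wins (a measure-zero tie,
   resolved deterministically). In the 3DP paradigm every patient is
   transplanted at arrival.

2. **Post-transplant progression.** An annual-cycle Markov chain over
   (NI, R, RO, TKA), started in NI at the patient's own surgery date, with
   checks at 52-week anniversaries; only checks inside the global 20-year
   window are simulated. Transitions are sampled from the unmodified row
   first; if the sampled destination would be the patient's third entry
   into an intermediate state (R or RO, one shared counter; an R→RO move
   counts as a new entry), the destination is replaced by TKA. The cap of
   two entries gives a 10-year transplant survival of 71% under the
   baseline matrix, in line with reported allograft survivorship — the
   stated rationale for the assumption.

3. **Costing.** Per patient: $30 for every *completed* week on the queue
   (a 104-week timeout accrues exactly 104 charges); the transplantation
   procedure at the transplant week ($8875 traditional, $7249 3DP); the
   per-event treatment cost of each state entered at an annual check (NI
   $0, R $2760, RO $1770, TKA $14,167, the latter once — TKA is
   absorbing); timed-out patients incur one TKA cost and no procedure
   cost. Patient evaluation costs are negligible and set to zero; no
   discounting (a rate hook exists and defaults to 0). Events are binned
   into calendar years (year *y* covers weeks (52(y−1), 52y]) and
   accumulated; summing a patient's cost events reproduces the experiment
   totals exactly, by construction.

## Parameters

| Parameter | Default | Units | Notes |
|---|---|---|---|
| n_patients | 1040 | patients | one per expected week of the horizon |
| horizon_years | 20 | years | 1040 weeks |
| patient_mean_interarrival | 1 | weeks | Exp interarrivals |
| donor_mean_range | (1, 5) | weeks | Uniform range of per-gap Exp means |
| wait_threshold | 104 | weeks | queue timeout to TKA |
| intermediate_cap | 2 | entries | third entry forced to TKA |
| n_replications | 10 | runs | arithmetic mean reported, SE as diagnostic |
| scenario factors | 1.5/0.5, 0.95/0.9, 1.43/1.11, 2.03775/0.4995 | — | R/RO/TKA scaling |

The worst/best combined factors are stored as exact products
(1.50·0.95·1.43 = 2.03775; 0.50·0.90·1.11 = 0.4995).

## Randomness and common random numbers

A master seed spawns named substreams per replication (patient arrivals,
donors, trajectory uniforms) via `numpy` `SeedSequence` spawn keys. Each
patient owns one row of pre-drawn uniforms, one per potential annual
cycle, consumed identically in every paradigm and scenario run under the
same seed. Trajectory sampling is inverse-CDF in the fixed state order
(NI, R, RO, TKA), so a larger quality factor can only move a given draw
away from NI and toward TKA: scenario comparisons are pathwise monotone
in the factor, and final TKA counts order exactly by factor under common
random numbers.

## Numerical and design choices

- **Scaling scope.** The quality factor multiplies every entry into R, RO
  or TKA in all three non-absorbing rows, with the complement routed to
  NI. This is the most literal uniform reading, preserves
  row-stochasticity, and reduces to the baseline at factor 1. Factors
  that would push a row's off-NI mass above 1 raise an error rather than
  clip, so scenario definitions stay exact (all shipped factors are
  feasible).
- **Intermediate-entry counting.** R and RO share one counter and R→RO
  counts as a new entry; the alternative episode reading (R→RO continues
  one episode) is a config switch (`r_to_ro_new_entry=False`). Neither row
  has a self-transition, so "remaining" in an intermediate state cannot
  occur.
- **Donor-mean mixing.** A fresh Uniform(1, 5) mean per gap is the
  default; `donor_mean_per_gap=False` draws one mean per replication.
  Both have mean 3 weeks.
- **Horizon censoring.** Patients still queueing at week 1040 (including
  those whose 104-week timeout would fall beyond it) are censored in
  place: waiting costs accrue to the horizon, no TKA is recorded.
- **Exact oracle.** `tka_probability_by_cycle` augments the chain with the
  entry count — states (health state, entries used), the (cap+1)-th entry
  redirected to TKA — and iterates the augmented kernel. It is validated
  against an independent exhaustive path enumeration to 1e-12 and against
  Monte-Carlo frequencies at 3 sigma with 50,000 replicates.
- **Money.** Costs are plain floats in USD; the bill of materials is
  summed with compensated (Kahan-style) summation so the itemized implant
  total is exact at printed precision.

## What the simulation does and does not emulate

The generator reproduces the *stated study conditions*: memoryless
arrivals, a stationary donor process, homogeneous patients, annually
discretized outcomes, and cost parameters taken as fixed constants. It
does not model donor-recipient compatibility, patient covariates or
pre-existing joint disease, utilities/QALYs, cost discounting or
inflation, post-TKA revision, or time-varying transition probabilities.
Passing tests therefore certify the internal consistency of the pathway
model and its implementation — not the external validity of the
parameters for any real transplant population.

Under these literal conditions the donor process (mean interarrival
3 weeks) supplies roughly one graft per three patient arrivals, so the
queue is persistently oversubscribed: most traditional-paradigm TKAs are
waiting-driven, and cumulative 3DP costs exceed traditional costs during
the first few years because the 3DP arm pays every procedure up front
while traditional patients are still queueing. Long-run cost dominance of
the traditional paradigm, and all cross-scenario orderings, are stable
across seeds.

## Problem sizes

Full-scale runs (1040 patients x 20 years x 10 replications, all nine
scenarios plus the traditional arm) complete in a few seconds on one CPU;
tests use reduced cohorts (50-400 patients) except for the end-to-end
checks, which run at full scale.
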