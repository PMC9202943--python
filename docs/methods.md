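# Methods

## Model and assumptions

A population of *M* homogeneous agents faces a repeated binary choice:
visit a venue or stay home. The venue has a hard capacity *B*; it is
crowded if and only if attendance strictly exceeds *B* (attendance equal
to *B* is still enjoyable). Agent *i* is characterized solely by a
per-period attendance probability *p_i(t)*; decisions are independent
Bernoulli draws, so total attendance *N(t)* is a sum of independent,
non-identical Bernoullis. There is no communication, no network, and no
explicit forecasting: agents adapt a single propensity parameter in
response to crowding signals.

The update is a clipped stochastic-approximation step of size
`-mu * (N(t) - B)`, applied

* only to the agents that attended (**partial information**), or
* to every agent (**full information**).

All updates are synchronous: every agent reacts to the same *N(t)*,
computed from the simultaneous draws of that period, and *N(t)* includes
the reacting attendee's own visit (no self-exclusion correction — the
attendance total is the published quantity). Probabilities are clipped to
the closed interval [0, 1]; the boundaries are reachable. Under partial
information *p = 0* is absorbing: an agent that never attends receives no
further information and is permanently excluded. We implement this
literal dynamic without any escape mechanism, since it is exactly the
segmentation phenomenon under study. Under full information no state is
absorbing (a crowding signal moves agents off 1, an uncrowded signal off
0).

Bookkeeping convention: `prob_history[t-1]` holds the probabilities in
force *before* period *t*'s draw, so the first row is the initialization,
`attendance_history[t-1]` is drawn from that row, and the final-period
statistics use *p(T)* (the product of T−1 updates) together with *N(T)*
drawn from it.

## Parameters

| symbol | meaning | default | notes |
|---|---|---|---|
| M | population size | 100 | headline study condition |
| B | capacity limit | 60 | crowded iff N > B; B > M = never crowded |
| mu | learning stepsize | 0.01 | per-period probability shift per unit of excess attendance |
| T | horizon (periods) | 300 | long enough for partial-information segmentation to be well developed, short enough that it is not complete |
| b | payoff scale | 1 | equilibrium module only; never enters the dynamics |
| runs | ensemble size | 1000 | headline Monte Carlo condition |

Initialization is i.i.d. Uniform(0, 1) — the maximum-entropy choice on
the admissible support, and consistent with the full-information
ensemble's mean fairness variance lying close to the uniform variance
(see below).

## Fairness statistic

Fairness is measured inversely by the *population* variance (divisor M)
of the final-period attendance probabilities,
`(1/M) * sum_i (p_i(T) - mean(p(T)))^2`, bounded by 0.25 (attained by a
half-at-0 / half-at-1 split). Across-run summary statistics likewise use
population variances (divisor n_runs); at n = 1000 the n/(n−1)
distinction is far below Monte Carlo noise, and using one convention
throughout keeps the summary consistent with the per-run formula.

A useful exact baseline: with `mu = 0` the dynamics freeze the
initialization, and the divisor-M variance of M uniforms has expectation
`(1 - 1/M)/12` (0.0825 at M = 100, not 1/12 — the finite-population bias
of the divisor-M estimator). The test suite asserts this closed form.

## Randomness and reproducibility

All randomness flows through `numpy.random.Generator` seeded by
`SeedSequence`. An ensemble rooted at base seed *s* gives run *k* the
child sequence `SeedSequence(s, spawn_key=(k,))`: runs are independent
and exchangeable, and any single run can be reproduced in isolation from
(s, k). Sensitivity-sweep cells extend the spawn key with their grid
coordinates (capacity index, stepsize index); the two regimes within a
cell share the cell root and therefore see identical initializations.
CSV/JSON exports embed the resolved parameter set and seed and write
floats at full (shortest round-trip) precision, so repeated invocations
with the same configuration are byte-identical.

## Equilibrium analysis

The one-shot game pays an attendee `b` if `N <= B` and `-b` otherwise;
staying home pays 0. `is_pure_nash` checks unilateral deviations with the
deviator's action flipped in the attendance count (a stayer who deviates
faces N+1). Exhaustive enumeration over all 2^M profiles is guarded to
M ≤ 20; for large populations the closed-form count `C(M, min(B, M))` is
reported, and the test suite verifies the closed form against brute force
for every (M, B) with M ≤ 12.

The symmetric mixed equilibrium is exposed under two conventions. The
classical value is `p = B/M`. The exact finite-population value solves
the indifference condition `P[Binomial(M-1, p) <= B-1] = 1/2` (an
attendee's expected payoff `b * (2 * P[uncrowded] - 1)` must vanish); the
CDF is strictly decreasing in p, so plain bisection converges, run to an
absolute tolerance of 1e-10. The two differ at small M (e.g. M=3, B=2:
1/√2 ≈ 0.707 vs 2/3) and converge for large M; both are reported rather
than adjudicated.

## Numerical and design choices

* **Clipping** maps below-0 to exactly 0.0 and above-1 to exactly 1.0
  (`numpy.clip`), making the absorbing-state logic exact rather than
  approximate.
* **Degenerate inputs**: `mu = 0` is allowed (frozen dynamics, used as a
  calibration case); `B = 0` and `B > M` are allowed; empty probability
  vectors and out-of-[0,1] probabilities raise `ValueError` — an
  out-of-range probability can only come from a broken update upstream.
* **Regime comparison** uses unpaired ensembles; the strict-dominance
  flag asks whether the largest full-information fairness variance is
  below the smallest partial-information one (max/min gap, no run-index
  pairing). At the headline conditions the two fairness distributions are
  separated by roughly twelve standard deviations, so this is the
  falsifiable reading of "fairer in every run".
* **Volatility diagnostics** compare the population variance of N(t)
  over the first and last 50 periods of a 300-period run (window
  configurable). These are orderings (late < early under partial
  information; no systematic decline under full information), not point
  targets.

## What the ensembles do and do not show

The Monte Carlo harness reproduces the published reference statistics of
the headline experiment at its stated scale (1,000 runs per regime):
means of final attendance and fairness within four standard errors of
the reference batch, variance-type statistics within 30% relative — the
reference values come from a single batch with unreported seeds, and
variance statistics of a leptokurtic attendance distribution carry a
per-batch standard error of several percent. Acceptance tests pin the
ensembles to a fixed, documented seed.

All of this concerns the model's own synthetic world: homogeneous agents,
a constant capacity, probability-based decisions with a fixed stepsize.
Passing tests demonstrate the internal dynamics (segmentation under
partial information, churn under full information, fairness ordering),
not that real venue visitors follow this calculus; heterogeneous
preferences, social ties, and time-varying restrictions are outside the
model.

## Known limitations

* Exhaustive equilibrium enumeration is exponential and deliberately
  guarded to M ≤ 20; only the count is available beyond that.
* The partial-information absorbing state means very long horizons drive
  fairness variance toward its 0.25 ceiling; T is a substantive parameter
  of the reported numbers, not a convergence knob.
* The simulator stores the full T × M probability history per run; for
  ensembles only the final period is retained, but single runs at very
  large M·T are memory-bound.
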