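# Methods

This note documents the models and conventions behind `pylorhythm`: what
each stage computes, the defaults and their units, the generative model the
synthetic data states, and the numerical choices made where a published
description leaves the implementation open. Nothing here claims an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Rhythm extraction

**Bursts.** A burst is a maximal run of spikes whose internal inter-spike
intervals are all strictly less than `burst_min_gap` (default 0.200 s); a
gap of exactly the threshold splits, because the criterion is "an
inter-burst interval of *at least* 200 ms". Runs with fewer than
`burst_min_spikes` (default 2) spikes are discarded outright — they do not
merge into neighbours and do not perturb cycle boundaries. The same rule is
applied to LP and PY by default (independently configurable); the published
rule is stated only for PD, so this is a package convention.

**Cycles and phases.** A cycle spans first PD spike to first PD spike of
the next burst; frequency = 1/period. Follower bursts are assigned to the
cycle containing their onset; when two bursts of one unit start in the same
cycle the first wins and the extras are counted in the assignment report.
An offset past the cycle end yields a phase > 1 and a spill flag rather
than an error. Phases are (event − cycle start)/period, so they are exactly
invariant under time translation and uniform rescaling (property-tested).
Missing units produce absent fields, never zeros, and serialise as empty
CSV cells.

**Period matching.** For latency comparisons at matched periods across
conditions, cycles are paired one-to-one by an optimal assignment
(`scipy.optimize.linear_sum_assignment` with infeasible pairs priced out):
the assignment first maximises the number of pairs with
|Δperiod| ≤ `period_match_tolerance` (default 0.02 s) and then minimises
the total discrepancy. A greedy nearest-neighbour scan was considered and
rejected: it is order-dependent and can strand feasible pairs, which an
exhaustive-search oracle on small instances exposes. The tolerance is a
package default — no published value exists — and is configurable and
reported with the results.

## Temperature and Q₁₀

Cycle temperature is the exact time-average of the piecewise-linear
temperature trace over the cycle (trapezoid through the native samples
plus interpolated endpoints), not the value at cycle start; at ramp rates
of ~0.05 °C/s the difference is negligible but fixing it makes results
deterministic in the trace's sampling rate. Outside the trace span the
nearest sample is used, with a warning.

Holding windows are maximal contiguous runs of cycles within
`holding_tolerance` (±0.3 °C) of a protocol target; a cycle eligible for
two targets goes to the nearer one; runs shorter than `min_window_cycles`
(default 10) are dropped so that grazing transits during ramps do not
count. Repeated visits to one target (e.g. a return to 11 °C) pool into
one steady-state row, labelled by target. Reported SDs are sample SDs
(ddof = 1).

The Q₁₀ fit is ordinary least squares of ln f on (T − T_ref)/10 over the
steady-state means, using each window's **measured mean temperature**
rather than its nominal target (this removes the small bias from the
in-band ramp tail at each hold). Q₁₀ = exp(slope), f_ref = exp(intercept),
with the log-space residual SD and slope SE reported. The two-point
endpoint estimator (f₂/f₁)^(10/(T₂−T₁)) is provided for comparison; on
noiseless synthetic data the two agree to < 10⁻³.

## Jag classification

The per-cycle frequency and temperature series are smoothed with centred
moving averages of 30 and 10 cycles respectively. At the edges the window
truncates to the available samples; for an even window the extra sample
comes from the past (the pandas convention — the brute-force oracle in the
tests pins this down). A trailing-window variant is available behind
`mode="trailing"` for sensitivity checks, since the published description
says only "moving average".

Cycle *i* ≥ 1 is classified from consecutive smoothed differences:
temperature *increasing* iff Δtemp > 0.01 °C/cycle, else *stable*;
frequency *decreasing* iff Δfreq < −0.002 Hz/cycle, *increasing* iff
Δfreq > +0.002 Hz/cycle, else *stable*. Both criteria are strict
inequalities ("more than"), and the boundary behaviour is tested with
bit-exact threshold differences. The first cycle is unclassified. The
whole recording is classified — ramps and holds alike — because the state
labels themselves define the segments. The jag statistics are
P(freq decreasing | temp increasing) and P(freq increasing | temp stable);
an empty conditioning set yields an absent probability, not 0/0.

## Phase constancy and group statistics

Per experiment, the mean phase of each event at each holding temperature
(holding-window cycles only) is fitted with an OLS line; slopes are
reported per °C and per 10 °C, negative = phase advance. Across
experiments, a Shapiro–Wilk gate at `alpha` selects a two-sided one-sample
t-test (normal) or Wilcoxon signed-rank test (non-normal) of the slopes
against zero. The published description mixes "one-sample" and "paired"
t-test language; against a zero null these coincide, and the one-sample
form is implemented. Bonferroni correction uses the number of tests
actually run in the session (falling back to `n_phase_tests` = 10, the
5-phases × 2-conditions battery). A 1000-replicate simulated-null suite
checks the family-wise error rate stays ≤ α.

Paired condition comparisons use the same normality gate on the
differences (paired t vs Wilcoxon, two-sided; zero-variance differences
are a flagged degenerate error). The three-condition design uses a one-way
within-subjects ANOVA computed from textbook sums of squares
(F = MS_cond/MS_error with df (k−1, (k−1)(n−1)); no sphericity correction
by default, matching the published uncorrected df, with Greenhouse–Geisser
available behind `correction="gg"`), cross-checked in the tests against an
independent implementation (pingouin). Tukey HSD uses the
studentized-range distribution with the within-subjects error term — no
installed package provides that variant, so it is implemented here. The
unpaired two-sample test defaults to Welch (pooled variance behind a
flag), since the published variance assumption is unstated.

## I_h measurement

I_h amplitude is |mean holding current in a steady window − mean in an
initial window| during a long (12 s) hyperpolarizing step. Defaults:
initial window 50–150 ms after step onset (excluding the capacitive
transient), steady window the last 1 s of the step; both configurable,
since the published windows are unstated. The measure is invariant to a
constant current offset. Percent block is the **mean of per-cell
reductions**, not the ratio of group means — the two differ whenever
amplitudes vary across cells, and a regression test asserts the
difference on a crafted example. Note that for a pure exponential with
τ = 2 s, a window mean taken 50–150 ms after onset already misses ~5 % of
the amplitude; the synthetic-fixture tests therefore place the initial
window at the step onset (no capacitive transient exists in the synthetic
trace), where the analytic window-attenuation error is ~0.8 %.

## Synthetic generator: the stated world

The generator emulates the experiment the analysis assumes, with defaults
fixed at the published operating point:

- **Protocol**: start 11 °C, five 2 °C steps to 21 °C; each step is a 40 s
  linear ramp plus a 200 s hold (ramp + hold = 4 min); 120 s initial hold;
  0.5 s temperature sampling. The ramp duration is an assumption (only the
  4-min step total is published) and is configurable.
- **Frequency law**: f(t) = f_ss(T(t)) − jag_gain·x(t) with
  f_ss(T) = f_ref·Q₁₀^((T−T_ref)/10). The adaptation state x tracks the
  non-negative warming rate with a first-order relaxation,
  dx/dt = (max(dT/dt, 0) − x)/τ_jag, τ_jag = 30 s — chosen to reproduce
  the described timescale (frequency depressed over the ~30 s of warming
  and the first ~30 s of stability). The form is phenomenological by
  design; no mechanistic equations are published. x is stepped with the
  exact exponential update for piecewise-constant rate; f is floored at
  0.05 Hz.
- **Cycles and spikes**: cycle boundaries are the integer crossings of the
  integrated frequency (linear interpolation on a 10 ms grid; the number
  of complete cycles equals ⌊∫f dt⌋, asserted as a conservation test).
  Within each cycle the units burst at their phase parameters (plus linear
  temperature drift evaluated at the cycle-start temperature), with
  `spikes_per_burst` evenly spaced spikes per burst — intra-burst
  structure is immaterial to the analysis (only first/last spikes are
  used) but fixed for determinism. Independent Gaussian jitter
  (default SD 5 ms) is added per spike from a single seeded RNG stream in
  the documented order PD, LP, PY.
- **Condition presets** (values at the published group means): saline —
  f_ref 1.2 Hz, Q₁₀ 1.7, phases PD OFF 0.19 / LP ON 0.40 / LP OFF 0.66 /
  PY ON 0.58 / PY OFF 0.87, LP OFF drift −0.007 per °C, weak adaptation
  (jag_gain 0.5 Hz per °C/s); Cs — f_ref 0.9 Hz, Q₁₀ 1.3, phases
  0.12/0.29/0.56/0.60/0.90, LP ON drift −0.005 and LP OFF −0.014 per °C,
  jag_gain 3.0; Cs+PTX — Cs-like frequency parameters but control-level
  Q₁₀ (1.7) with the strong adaptation retained. Spikes per burst
  (PD 5, LP 8, PY 6) are typical counts for these units at 11 °C. The
  jag_gain values are package choices (no published equivalent exists);
  at the 0.05 °C/s ramp rate they produce transient dips of ~0.025 Hz
  (saline) and ~0.15 Hz (Cs).
- **PD burst duration**: by default the PD offset follows the PD OFF phase
  parameter (duration scales with period, i.e. phase-constant); setting
  `pd_burst_duration` instead fixes the duration in seconds (e.g. the
  published 164 ms).
- **Clamp fixture**: I(t) = I_hold − A(1 − e^(−t/τ)) during the step, with
  optional Gaussian noise; defaults A = 1.5 nA, τ = 2 s, 12 s step.

**What a green synthetic test establishes — and what it does not.** The
generator shares the analysis' structural assumptions (exact phase
parameters per cycle, Gaussian jitter, a single adaptation timescale, no
missed or extra detected spikes, no unit dropout, no slow drift in f_ref).
Parameter recovery therefore validates the estimator implementations and
their numerical behaviour, not robustness to spike-sorting errors,
non-stationarity, animal-to-animal variability in waveform, or departures
from the exponential Q₁₀ law. Published cohort-level means, SDs and
p-values depend on the deposited recordings and are out of scope here.

## Reproducibility and budgets

Every stochastic step takes a seed; reports serialise with sorted keys and
floats rounded to 12 significant digits, and re-running with identical
inputs yields byte-identical JSON (tested). Cycle tables serialise at 17
significant digits and round-trip bit-exactly. In the test suite,
simulation-heavy Monte-Carlo suites run scaled down for the CI budget
(24 seeds for the jitter-recovery bias bounds instead of 200; 30
seed-matched replicates for the condition contrast; a 3-point seed-matched
ladder for jag monotonicity) with thresholds unchanged; the
family-wise-error simulation runs at its full 1000 replicates. The full
default-protocol simulate-plus-fit cycle takes ~0.3 s, and the whole suite
runs in well under a minute.
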