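# Methods

## Model

The tissue is a Moran population of fixed size *N*. Turnover events occur
at total rate *d·N*; tumor events at *r_S·X_S* (birth) and *d_S·X_S*
(death), so the waiting time to the next event is
1/(dN + r_S X_S + d_S X_S) and events are drawn by Gillespie's direct
method. A turnover kills a uniformly chosen cell and fills the vacancy
with a fitness-weighted division draw over the full pre-death composition
(the dying cell is *not* excluded from the numerators): the daughter is
Type 0 with probability r₀X₀(1−μ₁)/F, Type 1 with
(r₁X₁(1−μ_{S−1}) + r₀X₀μ₁)/F, Type S−1 with
(r_{S−1}X_{S−1}(1−μ_S) + r₁X₁μ_{S−1})/F, or a malignant Type S cell with
r_{S−1}X_{S−1}μ_S/F, where F = r₀X₀ + r₁X₁ + r_{S−1}X_{S−1}.

A malignant daughter does not fill the vacancy: X_S is incremented and
the draw repeats until a tissue daughter appears, so one turnover can
seed several malignant cells. A redraw cap of 10⁴ guards pathological
μ_S ≈ 1 inputs. Malignant cells below the hybrid switch (2*N* by
default) follow the full stochastic birth–death channels; extinction
simply returns the system to the pre-emergence regime. At the switch the
clone's extinction probability is ≈(d_S/r_S)^{2N} and the remaining
growth to the detection threshold *M* (10⁹ cells ≈ 1 cm³) is treated as
deterministic, Δt = ln(M/X_S)/(r_S − d_S). Tissue turnover continues to
be simulated during Δt (the tumor channels are suspended): the field
keeps evolving while the tumor grows, and it is the field at *detection*
that drives everything downstream. Surgery zeroes X_S, preserves the
tissue, and the run continues to a second detection; each phase is
censored at `max_time` (default 10⁴ time units), with censored runs
flagged rather than dropped.

The spatial variant keeps the identical event algebra but restricts the
division draw to the von Neumann neighbourhood of the death site
(wall boundaries, no wraparound; 2 candidates at corners, 3 at edges,
4 in the interior). Death sites are uniform over the lattice — the exact
spatial analogue of the well-mixed uniform death by type count. Type S
cells are never placed on the lattice; they disrupt tissue architecture
and are tracked as an off-lattice count. When only *N* is given the
lattice defaults to the square ⌈√N⌉×⌈√N⌉ (an error if not exact).

## Parameters

| name | meaning | default |
|---|---|---|
| N | tissue size (cells) | — |
| d | turnover rate (events per cell per time unit) | 1 |
| r0, r1, rS1 | division-draw fitness weights (dimensionless) | 1 |
| rS, dS | malignant birth/death rates (per cell per time unit) | 1.5, 1.0 |
| mu1, muS1, muS | per-division mutation probabilities | 0 |
| detection_threshold | malignant count at detection | 1e9 |
| hybrid_switch | deterministic-growth switch, multiple of N | 2 |
| max_time | per-phase censoring horizon (time units) | 1e4 |

One model time unit is the reciprocal of the turnover-rate scale; the
calibration to calendar time happens only at fitting, where one unit is
one month, so a fitted d_S reads directly as tissue turnover cycles per
month. A configurable threshold supports the late-diagnosis variant
(10¹⁰ cells). r_S ≤ d_S is allowed but warned against: the malignant
clone then has no net growth and runs essentially always censor.

Randomness: every run derives a single 31-bit kernel seed (recorded in
its outcome) from the caller's seed or Generator; full runs split it
into per-phase streams via `SeedSequence`. Identical seeds replay
bit-identically. The Gillespie loops are JIT-compiled with numba; the
step-level functions (`turnover_step`, `division_distribution`, …) are
plain Python/NumPy with the same algebra and are the ones exercised
against the exact Markov-chain oracles.

## Pattern classification

At detection the tissue is labelled by strict thresholds: one type
>90% is dominance; two types each >40% pairwise co-dominance; all three
>30% triple co-dominance; dominance takes precedence over the pair rule,
which takes precedence over the triple rule (overlaps are possible at
the pair/triple margin). Compositions matching no rule get the OTHER
label — the printed rules do not cover, e.g., a 70%/30% split, and
totality requires a label; censored runs are NO_CANCER. Mid-sweep
detections make OTHER a real, not merely theoretical, outcome: a
successful malignant lineage reaches the threshold only ~30–45 time
units after emergence, while near-neutral tissue sweeps take hundreds to
thousands of units, so detection regularly freezes the field partway
through a sweep. This is why the scaled-down grid scans report more
distinct classes (6 well-mixed, 8 spatial including NO_CANCER) than the
three/seven archetypes one obtains when every detected composition falls
cleanly into a dominance or co-dominance class.

## Survival statistics and fitting

Kaplan–Meier curves come from the product-limit estimator (lifelines)
on right-censored samples; two curves are compared with the Mantel-Cox
log-rank test. A curve is summarised by the times at which cumulative
recurrence first reaches 0%, 4%, …, 100%; the 0% point maps to time zero
and quantiles beyond the curve's reach are flagged missing. The fitting
objective is the mean of squared natural-log residuals (log-MSR) between
the simulated and clinical percentile times over the shared usable
quantiles (missing or zero-time points excluded); the log base is
unstated in the source material — natural log is used, and the choice
only rescales the objective, leaving the argmin unchanged. The companion
sum (log-SSR) is reported alongside, and the bundled profile fixture's
SQ column is on the sum scale.

Candidate evaluation adds one guard on top of log-MSR: quantiles the
clinical curve reached but the simulated cohort did not are imputed at
the candidate's censoring horizon — a lower bound on the unreached
time — before scoring. Without this, a candidate that recurs in only a
few runs is scored on its few early percentiles alone and can spuriously
beat the truth. Candidates with no events at all, or no overlapping
usable quantiles, receive a penalty objective of 10⁶ so random search
stays total.

Fitting draws candidates uniformly within bounds (log-uniformly for the
mutation probabilities), simulates a cohort per candidate (each run's
recurrence time is an event; non-recurring runs are censored at the
horizon), and returns the argmin with a log-rank p value between the
clinical sample and a fresh cohort at the best parameters. Default
ranges bracket the fitted profiles: r₁, r_{S−1} ∈ [0.85, 1.15],
r_S ∈ [2, 9], d_S ∈ [1, 4.5], log₁₀μ ∈ [−5, −2]. N, d (1/month) and
r₀ = 1 are fixed structural values — no fitted d is reported in the
profile table, and r₀ is the fitness reference. The engine defaults to
the lattice at N = 2500; a well-mixed escape hatch exists for desk-scale
work. The candidate budget (n_samples = 1000) and cohort size per
candidate (n_runs = 200) are configurable; the test suite uses 500/100
at N = 100.

## Synthetic cohorts

`synthesize_cohort` emulates a clinical DFS export: each patient is one
full simulated run at known "true" parameters; a chosen fraction is
administratively censored at a uniform random time below the event time
(loss to follow-up). It reproduces the right-censored, months-scaled
structure of real DFS tables but none of their other features — no
cohort heterogeneity across patients, no age/stage stratification, no
metastatic or progression events, no measurement rounding. Passing the
recovery test therefore shows the estimator is consistent under the
model's own data-generating process, not that real clinical fits are
unbiased.

The parameter-recovery experiment uses truth values (N = 100, r₁ = 1.0,
r_{S−1} = 1.1, r_S = 3.0, d_S = 1.5, all μ = 10⁻²) chosen so that every
patient recurs within the 400-month horizon and the recurrence time is
dominated by the deterministic growth segment ln(10⁹/2N)/(r_S − d_S),
which is what makes the net growth rate identifiable from curve shape;
sampling ranges are centred on the truth (±0.1 on fitness, ±1.0 on r_S,
±0.5 on d_S, ±0.5 dex on mutation rates). With ~20% of runs censoring at
the horizon (slower truths) the objective becomes noisy enough that the
argmin wanders by ±40% in net growth.

## Numerical choices and degenerate inputs

- Probability normalisation of every draw distribution is algebraic
  (F/F); tests assert it to 1e-12.
- A zero total event rate (d = 0 with no tumor) or zero total fitness
  raises a frozen-system error rather than looping.
- Strict threshold comparisons in the classifier mean boundary
  compositions (exactly 90/40/30%) fall to the next rule.
- Percentile lookup uses a 1e-12 tolerance so exact curve levels
  (e.g. S = 0.75 at the 25% point) are matched despite float rounding.
- The profile fixture is integrity-checked by SHA-256 on load.
- Trend experiments use r_S = 1.5 with d = d_S = 1 as the supercritical
  base; desk-scale problem sizes throughout the suite are N = 300
  (well-mixed grids and trends), 20×20 (lattice grid), N = 100
  (fitting), with 1–3 replicates or 100–500 runs per condition.

## Known limitations

- Intermediate Type K compartments are not modelled explicitly; a low
  μ_{S−1} stands in for extra steps, as in the source model.
- No metastasis, no cell migration, no 3D or hexagonal lattices, no
  periodic boundaries, no Cox regression or competing risks.
- The branching clone interacts with the tissue only through its size;
  there is no physical displacement of tissue by the tumor.
- Whether the original implementation simulated tissue turnover during
  the deterministic tumor-growth interval, and whether a vacancy redraw
  can seed multiple malignant cells, are not stated in the source
  description; the choices here (turnover continues; multiple births
  possible, capped) are documented above and localised in the kernels.
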