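# Methods

This note documents the models, algorithms, numerical choices and
limitations of `vancomst` in the way they are implemented, including the
design decisions that were genuinely open and the reasoning behind them.

## Cohort model

A *treatment episode* is one patient's contiguous intravenous vancomycin
course.  Doses of the same patient separated by ≥ 7 days (168 h; a gap of
exactly 168 h splits) start a new episode.  All times are hours since the
episode's first dose; input CSVs may carry ISO-8601 timestamps, converted on
read.  Duplicate concentrations at identical timestamps are kept as distinct
observations (real-world replicates).

**Troughs.**  An observation is a trough iff it falls within
[s − 2.5 h, s + 0.5 h] of the scheduled start *s* of some dose.  When no
scheduled time is recorded, the actual administration time is the only
observable surrogate and is used as the anchor.  Observations later than
0.5 h after the final scheduled dose can match no window and are never
troughs.  The window is deliberately wide on the early side because
real-world trough draws precede the dose by up to a couple of hours.

## Derived covariates and imputation

* Ideal body weight (Devine): 45 kg (F) / 50 kg (M) + 1 kg per cm of height
  above 150 cm.
* Cockcroft-Gault CrCl (mL/min) on ideal body weight with creatinine in
  µmol/L: `((140 − age) · IBW / SCr) · 0.85 if female`, clamped at 0.
* CKD-EPI creatinine eGFR (mL/min/1.73 m²): the 2009 equation with the race
  coefficient omitted is the default — the cohorts this tool targets do not
  record race — and the 2021 race-free refit is selectable
  (`version="2021"`).
* Treatment day d = ⌊t/24 h⌋ + 1 relative to the episode's first dose.

Missing laboratory values are imputed with the nearest value within ±48 h;
on an exact tie the earlier value wins, because it is the one that was
available in real time.  Other covariates take the value of the same day,
else the first available among the days −1, +1, −2, +2 relative to the query
day.  When freezing covariates at a timeframe start, a value still missing
after these rules falls back to the closest value anywhere in the episode;
if none exists the timeframe is excluded.

## Timeframes

Within each ICU period, time is split into maximal spans of constant RRT
status (timeframes never straddle an RRT boundary).  Candidate starts are
treatment initiation and every concentration time; each candidate extends to
the next **two** concentrations in the same span (those two are the
timeframe's targets), and spans longer than 72 h are discarded.  Covariates
are frozen at the start — the information available for real-time
forecasting — so nothing after the start can influence them.

## PK engine

Models are declarative: CL and V are arithmetic expressions over covariate
names (a restricted AST evaluator: arithmetic, comparisons, conditionals and
exp/log/sqrt/min/max — no general code execution), with log-normal IIV on CL
and V (correlation fixed at 0 unless declared) and a proportional, additive
or combined residual-error model.  Registries load from YAML files; the
required covariates of a model are inferred by scanning its expressions.

Concentration under intermittent infusion uses the closed-form superposition
solution: with k = CL/V and R0 = amount/duration, a dose contributes
(R0/CL)(1 − e^(−k t′)) during the infusion and decays mono-exponentially
after it; doses add by linearity.  The default infusion duration is 1 h when
absent from input — common vancomycin practice.  The engine is verified in
the tests against an independent piecewise high-order ODE integration to
< 1e−6 relative error.

**MAP estimation.**  Individual effects η = (η_CL, η_V) minimize

    Σ_obs [ (y − f(η))² / σ²(f) + ln σ²(f) ]  +  ηᵀ Ω⁻¹ η

with σ²(f) evaluated at the model-predicted concentration (the convention of
standard estimation systems).  Optimization is quasi-Newton (BFGS) from
η = 0 with two seed-jittered restarts and an objective tolerance of 1e−8;
etas with zero omega are held fixed.  The returned mode is never worse than
the prior mode.  Two consequences worth knowing: the ln σ²(f) term pulls
predictions very slightly downward even for data exactly at the population
prediction, and trough-only designs leave a shallow CL/V trade-off ridge
along which the prior picks the estimate.

## Error metrics and UBM

PPE = (measured − predicted)/measured × 100 % (positive = underprediction);
PAPE = |PPE|.  Means are taken over all observation-level errors pooled
across timeframes; a per-timeframe-then-pool alternative is available behind
`per_timeframe=True` (the two differ only when timeframes carry unequal
observation counts).  The UBM minimizes |mean PPE| + mean PAPE; ties break
toward the lower registry index, deterministically.

## MST: labelling, CART, CV, GA

Each timeframe's label is the subset model with the lowest timeframe-mean
PAPE of population predictions (ties → registry order).  The CART is
scikit-learn's Gini classifier restricted to depth ≤ 3 with a minimum leaf
fraction of 0.05 (guards against degenerate splits), exported into the
package's own serializable tree with "< threshold goes left" semantics;
thresholds fall at midpoints between adjacent observed values, so training
behaviour is identical.  Labels are encoded as registry indices so the
classifier's majority-tie rule reproduces the registry-order tie-break.

Cross-validation folds are grouped by treatment episode — all timeframes of
an episode share a fold — so concentrations of one course never inform their
own held-out evaluation.  Fold assignment is a seeded shuffle of episodes
dealt round-robin; with fewer episodes than folds it falls back to
timeframe-level folds (still seeded).  A subset's fitness is the mean over
folds of the held-out pooled PAPE under the fold-trained tree's assignments.

The genetic algorithm evolves subset bitmasks: tournament selection (size
3), uniform crossover (rate 0.8), per-bit mutation (rate 1/registry size),
elitism 2, population 50 and 100 generations by default.  Empty offspring
are repaired by switching one random bit on; fitness values are cached per
subset (folds are fixed per search, so fitness is a pure function of the
mask), and the best-ever subset is returned with its tree refitted on all
timeframes.  The search is bit-reproducible from its seed.  Desk-scale runs
in the tests and the acceptance script use population 16–24 and 12–20
generations, which exhausts the small registries involved (≤ 31 subsets)
many times over.

The published reference tree is shipped as data:
eGFR < 31 → Staatz; eGFR ≥ 31 on day 1 → Kim; later days with
eGFR ≥ 125 → Kim; otherwise → Zhou.  Its exact split order beyond these four
rules is not uniquely determined by the available description; the encoded
tree is one consistent depth-3 realisation.  The six YAML files under
`models/` carry *synthetic placeholder* parameters (marked as such in each
file) so the registry loads and the pipeline runs end-to-end; all automated
tests use synthetic specs and never depend on those numbers.

## Forecasting evaluation

Episodes qualify when they started in the ICU, have ≥ 3 concentrations, the
third is a trough, and no required covariate is missing.  The third
concentration is predicted using only information available by the second
measurement: covariates frozen at that time and, depending on the setting,
MAP conditioning on none, the first, the second, or both prior
concentrations.  Doses administered between the second and third measurement
are part of the known prospective schedule and are included.  Setting 4
conditions on the second observation alone, carrying nothing forward from
the first.  MAP failures are recorded and excluded from the means with their
count; report means are recomputed bit-identically from the per-task log in
the tests.

## Synthetic cohorts

The generator emulates the adult-ICU structure the pipeline assumes: ~76 %
male, age ≈ N(63, 10) clipped to [18, 95], sex-specific heights, log-normal
weight (median 82 kg), log-normal baseline creatinine (median 85 µmol/L)
evolving as a bounded geometric random walk (daily log-step σ = 0.15,
clipped to [20, 800] µmol/L), RRT in 30 % of episodes, and discretized
log-normal treatment durations (median 8 days, range 3–21).  Dosing follows
the guideline rule re-evaluated daily on a 12 h grid: 1,000 mg q12h when
CrCl > 50 mL/min, otherwise a single load with redosing whenever the
predicted concentration falls below 20 mg/L — a simulator heuristic standing
in for clinician judgment.  Sampling is trough-dominant: one draw before the
first dose of each day, 0.3–2.3 h ahead of it (inside the trough window).
Residual noise is proportional with σ = 0.15, a typical assay-plus-model
magnitude for vancomycin.

Each patient's concentrations come from the generating model of their
baseline-eGFR region, with individual CL and V fixed at baseline covariates
for the whole episode.  The recorded creatinine series still evolves, so
later timeframes see covariates that drift from the PK actually generating
the data — a deliberate, realistic source of model error in the default
configuration.

**Planted subgroup scenario.**  `plant_subgroup_scenario()` draws baseline
eGFR uniformly over (8, 180), switches the creatinine walk off (so region
membership is unambiguous all episode), and assigns one generating model per
eGFR region.  The default trio shares V = 0.7·weight and has CL-vs-eGFR
lines that intersect exactly at the planted thresholds (2.8 − 0.045·eGFR,
0.045·eGFR, and 0.2·eGFR − 19.375, crossing at ≈ 31 and 125), with small IIV
(ω_CL = 0.01, ω_V = 0.005).  These choices make the best-model label flip
precisely at the planted boundaries and keep subgroup membership — not
individual variability — the dominant signal, which is the property the
fixture exists to plant.  What passing recovery tests show is therefore that
the pipeline finds subgroup structure *when it exists and is identifiable*;
they do not show that real hospital data contain such clean structure, that
covariate drift never blurs subgroup membership, or anything about
two-compartment kinetics, assay differences, or dosing behaviour beyond the
simulated guideline.

## Problem sizes and numerics

Tests and the acceptance script run the pipeline at desk scale — 40–80
synthetic patients (≈ 200–400 timeframes), registries of 4–6 models,
GA populations of 16–24 over 12–20 generations, 150–200 simulated
individuals for MAP recovery — sizes chosen so the full suite completes in
about a minute while every recovery signal stays far from its decision
threshold.  Numerical tie-breaks are deterministic throughout (registry
order for model ties, earlier value for imputation ties, seeded RNGs for
everything stochastic).  Degenerate inputs return empty results rather than
raising where the domain allows it (an episode with no valid timeframe, a
series with no imputable value); domain violations (non-positive doses,
concentrations, creatinine) raise typed errors.

## Known limitations

* One-compartment kinetics only; no covariance between η_CL and η_V unless
  declared; no uncertainty on the MAP estimates.
* The shipped `models/*.yaml` parameters are placeholders, not transcribed
  published estimates.
* The generator freezes individual PK at baseline covariates; it does not
  model within-episode clearance dynamics (e.g. dialysis sessions changing
  CL hour-to-hour), organ-failure trajectories or ECMO.
* Whether RRT-subset timeframes should train the same tree or a separate one
  is left to the caller; the default pools them with `rrt_active` offered as
  a split covariate.
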