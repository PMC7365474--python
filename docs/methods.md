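# Methods

This note records the model as implemented, the unit conventions, the
sampling algorithms, the design choices made where the published
description leaves the design open, and what the shipped tests do and do
not establish.

## Model structure

A woman's course is a five-compartment process: healthy → undetected
cancer → detected cancer, with other-cause death reachable from any living
compartment and cancer death only from the detected one.  Once detected,
she remains "detected" for life; there is no cure-return transition.
All times are measured in years from study start; the burn-in places study
entry at *t* = 0 with simulation starting at *t* = −6.

### Rates and laws

| quantity | form | defaults |
|---|---|---|
| cancer incidence *c_a*(*t*) | Gaussian bell in attained age, mass 0.1967·γ | γ = 1.54, μ = 76.86 y, σ = 19.5 y |
| other-cause mortality *h_a*(*t*) | c₀·exp(c₁·age) | c₀ = 0.208×10⁻⁵/y, c₁ = 0.1196/y |
| tumor growth | *d*(*t*) = *d*max·(*d*₀/*d*max)^exp(−12·k·(t−t₀)) | *d*₀ = 0.0124 mm, log *k* ~ N(−2.9, 0.71²) (month⁻¹), *d*max ~ unif(1, 128) mm |
| detection sensitivity *S_j*(*d*) | expit((*d* − *b*_{j2})/*b*₁) | *b*₁ = 1.5 mm; *b*_{j2} = 6.33 (mammography), 18.5 (physical), 20 (self), 40 (before-study) mm |
| cancer mortality after detection | *k*^α·*d*_de^Z·ω·τ^{ω−1} | ω = 1.272, Z = 1.06, α = log(Q/15^ω)/log(k_m) = 3.19, Q = 0.0067 |

Derived constants: k_m = exp(μ_k + σ_k²/2) = 0.0708 month⁻¹;
α ≈ 3.19 (the 15 in its definition is a fixed reference diameter in mm,
not a free parameter).  The scenario multiplier on *c_a* is 1 at baseline
and 5 in the high-risk population.

### Time units

The growth formula is evaluated with *t* in years and *k* in month⁻¹; the
explicit factor 12 is the unit conversion, so on a month clock the
exponent is exp(−k·months).  An alternative half-rate reading
(exp(−k/2·months)) is available through the configurable
`growth_exponent_factor`; it is not the default because it cannot
reproduce the calibration trial's recorded outcomes (first-year diagnosis
counts fall by ~40% and diagnosis ages shift late).

The post-detection mortality clock τ also runs in years.  This is the
only reading consistent with the trial's outcomes: on a month clock the
same hazard constants imply ≈2,000 breast-cancer deaths per arm over 25
years and mean ages at cancer death near 58.5, versus the recorded ≈500
deaths and ages near 61; on the year clock the model produces ≈550–640
deaths and ages near 62.  The hazard and its Weibull survival
exp(−k^α·d^Z·τ^ω) are algebraically unit-agnostic; only the engine's
conversion encodes this choice.

## Sampling algorithms (all exact)

* **Stage 1.**  Onset and other-cause death are independent competing
  clocks with closed-form cumulative hazards (Gaussian CDF and
  exponential).  Both latent times are drawn by analytic inversion
  (`ndtri` for onset; a log formula for death) and the earlier one is the
  realized first event — distributionally identical to first-event
  sampling of the joint hazard, with no time stepping and no simultaneous
  events.  The exact Gaussian-CDF integral of *c_a* replaces any
  polynomial approximation; it is both faster and error-free.
* **Stage 2.**  Detection can only occur at discrete exam dates, where the
  current Gompertz diameter sets an independent Bernoulli success
  probability per modality.  Between exams nothing stochastic happens to
  an undetected tumor, so the engine evaluates exams directly (in column
  blocks, retiring women at their first success) rather than looping over
  days; this is exactly the law of a 1-day-stepped simulation, verified by
  a Kolmogorov–Smirnov test against a literal daily-thinning oracle.  The
  within-day rule when an exam and the death clock collide on a calendar
  day (day = floor(365.25·t)) is detection-first, config-exposed.
* **Stage 3.**  The cancer-death time is a closed-form Weibull inverse
  draw from the detection date.  The other-cause clock drawn in Stage 1
  keeps running (its hazard does not depend on disease stage), and the
  earlier clock wins.

One root seed spawns named substreams (numpy `SeedSequence` spawn keys)
per purpose × batch × replicate × arm.  Cohorts are built in fixed-size
batches keyed by batch index, so enlarging a population appends new
batches without perturbing existing ones; within a batch the draws are a
deterministic function of the seed, so every run is bit-reproducible.

## Trial design and burn-in

The standard design: 44,918 women (mammography arm: annual mammography
plus physical exam at years 0–4) and 44,917 (control arm: ages 40–49 a
single physical exam at entry, ages 50–59 annual physical exams at years
0–4), ages uniform on [40, 59] in both arms, horizon 25 years.  The
trial's exact age-stratified arm sizes are not published numerically; the
even split with uniform ages is the default and is config-replaceable.

Every candidate starts healthy six years before entry.  During burn-in
the only detection channel is the before-study check
(*b*_{b2} = 40 mm), annually (a coarse screen that removes candidates
with conspicuous tumors, mirroring trial eligibility).  Candidates
diagnosed or dead before *t* = 0 are ineligible and are replaced by
rejection sampling; women whose tumor started but stayed undetected enter
the trial as prevalent undetected cancers (~0.8% of enrollees at
defaults).

In-study, both arms additionally carry a self-exam channel
(*b*_{s2} = 20 mm) — the model's only non-screen route to diagnosis,
i.e. symptomatic surfacing.  Its cadence is not published.  It was fixed
at 26 checks per year by matching the recorded *control-arm* outcomes
(first-year diagnoses: simulated median 167, interquartile range
[160, 177], recorded 170), in the same spirit as the published
calibration, which used only control-arm data.  Self exams sit at
mid-interval offsets so they never coincide with scheduled visits.

## Paired replicates and the benefit/harm layer

Each cancer-acquiring patient (attributes plus one onset time, sampled
conditional on onset before the horizon) is simulated repeatedly in both
arms.  Within a replicate pair the onset, the other-cause clock and the
burn-in detection draws are shared across arms; in-study detection trials
and the cancer-death draw are arm-specific.  Sharing the onset removes
lead-time bias from survival comparisons and sharing the death clock
removes most between-arm noise (the paired benefit estimator's variance
is verified to be no larger than the independent-cohort design's).

Subcohorts use the published sextile boundaries for *k*
(0.0275/0.0400/0.0543/0.0726/0.104 month⁻¹) and *d*max
(22.36/43.36/64.16/85.05/106.4 mm) as fixed constants — boundary values
fall in the lower class — crossed with onset before (*t* < 0), during
(0 ≤ *t* < 5) or after (*t* ≥ 5) the study: 108 cells.

Per cell the package reports: per-thousand differences in diagnoses and
in all-cause deaths; the per-thousand difference in the probability of
dying of other causes before this cancer (competing-risks integral from
detection, treatment effectiveness floored at α = 2.5, evaluated by
Gauss–Legendre quadrature and cross-checked against adaptive quadrature
and Monte-Carlo); the Cox proportional-hazards ratio for arm membership
with time from onset (statsmodels `PHReg`, Breslow ties — continuous
times make ties measure-zero anyway); Pearson χ² significance of the
diagnosis difference (two-sided 0.05, no multiple-testing correction, as
flagged in the output); and percentile bootstrap intervals that resample
patients with their full replicate sets (500 replicates by default).

A max-over-cells summary of the benefit grid is upward-biased under cell
noise; the acceptance computations therefore average the grid over
replicate experiments before taking the maximum (20 experiments of
10,000 patients × 10 pairs), which converges near 1.1–1.3 percentage
points in the top aggressiveness/size cells.

## Calibration

The three data-driven parameters (*b*_{b2}, γ, Z) minimize squared
deviations between simulated and recorded control-arm outcome vectors
(default granularity: annual diagnoses years 1–5, diagnoses years 6–25,
cancer deaths at 25 years; any labeled vector plus extractor can be
substituted).  Only the control arm is ever simulated.  Evaluations use
common random numbers so the optimizer sees a deterministic surface, and
the optimizer minimizes the squared distance of the replicate-averaged
outcome vector: the per-realization expected objective equals
‖EX − Y‖² + Σᵢ var(Xᵢ), and at N = 5,000 its parameter-dependent variance
term (~400) dwarfs the ~30–100 identification signal and drags the argmin
toward parameters producing fewer, less variable counts.  Averaging
outcomes first shrinks that term by the replicate count.  The search is a
coarse grid followed by Nelder-Mead in box-normalized coordinates,
alternated with full-range coordinate sweeps (the CRN surface is jagged
and a simplex can strand a weakly identified coordinate — in practice
*b*_{b2} — at a box edge).  Synthetic-recovery experiments at N = 5,000
and 20 replicates per evaluation recover (40, 1.54, 1.06) within 20%
when three independent calibration replicates are averaged; single runs
recover γ and Z almost always and *b*_{b2} in roughly three quarters of
seeds, which is the honest precision of this estimator at that population
size.

## What the synthetic data does and does not show

All inputs are generated by the simulator itself; there is no external
data dependency.  The generator reproduces the *model's* world: perfect
adherence to exam schedules, a single tumor per woman, no loss to
follow-up or staggered entry, no treatment-type structure, calendar-free
hazards.  Tests passing therefore establish internal correctness
(samplers match their analytic laws, statistics match independent
oracles, qualitative benefit/harm patterns emerge) and reproduction of
most published summary numbers — not transportability to other trials or
to real screening programs.

Residual misfit to the calibration trial, deliberately left visible in
two red acceptance-level tests rather than absorbed by re-tuning fixed
parameters: (1) full-size first-year mammography-arm diagnoses center
near 208 against the recorded 253 — the prevalent pool detectable only by
mammography (≈6–17 mm) is structurally too small under this reading of
the growth/burn-in mechanism, and no self-exam cadence moves it without
breaking the control arm; (2) mean ages at cancer death among
screening-phase cancers run ≈0.6–1.4 years older than the recorded
60.97/60.70, with the ±0.5-year band of the corresponding check also
tighter than the single-run sampling noise at 10,000 women per arm.

## Numerical details

* Diameters, hazards and survivals are evaluated in double precision;
  Weibull survival may underflow to exactly 0 for extreme (large, fast)
  tumors, which downstream code treats as certain death.
* An exam falling at exactly the onset instant sees a not-yet-grown tumor
  and is skipped (measure-zero boundary).
* Degenerate inputs are rejected with `ValueError`s: non-positive
  diameters or rates, inverted intervals, uniforms outside (0, 1),
  unknown modalities, empty cohorts.
* Census/occupancy queries are left-continuous: an event at exactly *t*
  has not yet taken effect at *t*, so the *t* = 0 census shows entry-day
  screen detections still in the undetected compartment.
* Cox fits with no events, a single arm, or no positive durations return
  NaN rather than a fabricated ratio; replicates in which the shared
  death clock precedes the shared onset carry no survival-from-onset
  information and are excluded from the Cox risk sets (they remain in the
  per-thousand denominators).
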