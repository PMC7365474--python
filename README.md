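# bcham

An individual-based stochastic model of breast cancer incidence, screening
detection and mortality, built around unmeasured tumor heterogeneity.  The
package simulates the Canadian National Breast Screening Study (CNBSS) — a
randomized trial of 89,835 women aged 40–59 followed for up to 25 years —
and quantifies when mammography screening helps (earlier detection of
aggressive tumors) and when it harms (overdiagnosis of tumors that would
never have mattered).

It is written for modelers and biostatisticians who want a fast, tested,
reproducible implementation of this class of natural-history
microsimulation: every sampler is an exact inverse-CDF draw or a Bernoulli
trial at a scheduled exam, every rate has a closed-form cumulative, and a
full-size trial arm (≈45,000 women, 25 years) simulates in well under a
second.

## The model

Each woman carries three individualized factors: her age at enrollment
*a* ~ unif(40, 59), a tumor-aggressiveness constant *k* with
log *k* ~ N(−2.9, 0.71²) (month⁻¹), and a maximum tumor diameter
*d*<sub>max</sub> ~ unif(1, 128) mm.  Her life course moves through five
compartments — healthy, undetected cancer, detected cancer, cancer death,
other-cause death — governed by:

* **Onset.** A bell-shaped incidence rate in attained age,
  *c<sub>a</sub>*(*t*) = 0.1967 γ / (σ√2π) · exp(−(*t*+*a*−μ)²/2σ²) with
  μ = 76.86 y, σ = 19.5 y and fitted scale γ = 1.54.
* **Growth.** Gompertz growth on the diameter scale,
  *d*(*t*) = *d*<sub>max</sub>(*d*₀/*d*<sub>max</sub>)^exp(−12 *k* (*t*−*t*₀)),
  from a single cell *d*₀ = 0.0124 mm toward the asymptote *d*<sub>max</sub>.
* **Detection.** Logistic size-dependent sensitivity per modality,
  *S<sub>j</sub>*(*d*) = expit((*d*−*b*<sub>j2</sub>)/*b*₁), with
  half-detection diameters 6.33 mm (mammography), 18.5 mm (physical exam),
  20 mm (self exam) and 40 mm (before-study check), applied as an
  independent Bernoulli trial at every scheduled exam.
* **Mortality.** Other-cause death at 0.208×10⁻⁵ exp(0.1196 · age) per
  year; after detection at size *d*<sub>de</sub>, a Weibull
  cancer-mortality hazard *k*^α *d*<sub>de</sub><sup>Z</sup> ω *t*^(ω−1)
  with ω = 1.272, Z = 1.06, and treatment effectiveness
  α = log(Q/15^ω)/log(*k*<sub>m</sub>) = 3.19.

Three parameters (γ, Z and the before-study constant *b*<sub>b2</sub>) are
calibration products of the CNBSS control arm; the package ships them as
defaults and also ships the least-squares calibration machinery that
re-estimates them from control-arm outcome tables.

The benefit/harm layer simulates each cancer-acquiring woman repeatedly in
both trial arms with an identical onset time (common random numbers),
stratifies the 108 subcohorts (sextiles of *k* × sextiles of
*d*<sub>max</sub> × onset before/during/after the study), and reports
survival benefit, excess incidence per thousand, the probability of dying
of other causes first (treatment effectiveness floored at α = 2.5), Cox
hazard ratios timed from onset (no lead-time bias), χ² significance and
patient-level bootstrap intervals.

## A worked example

```python
from bcham import trial
from bcham.params import ModelParams

result = trial.run_trial(
    trial.cnbss_design(mammography_size=10_000, control_size=10_000),
    ModelParams(), seed=42)
print(trial.summarize_ages(result))
```

Running `python examples/02_trial_simulation.py` (which is this run, plus
the annual series) prints:

```
first-year diagnoses (10k per arm):
  mammography 43, control 37

25-year totals:
             diagnoses  cancer_deaths
control            839            146
mammography        873            151

screening-phase age summary:
        arm  n_diagnosed...  mean_age_at_diagnosis  ...  mean_age_at_cancer_death
mammography             132                  53.21  ...                     61.43
    control             132                  54.25  ...                     60.39
```

At full trial size the first-year counts scale to roughly 210 and 168
against the recorded 253 and 170, and the screening-phase mean ages at
diagnosis (53.2 / 54.3 here) sit close to the recorded 53.08 / 53.44: the
mammography arm finds its cancers almost a year earlier and smaller, which
is exactly the lead time that the paired benefit analysis then converts
into (small) survival differences.  The other examples walk the
natural-history primitives, the 108-subcohort benefit/harm grid with the
treatment-effectiveness sweep, and a calibration recovery.

## Command line

```bash
bcham simulate  --seed 1 --out run/            # two-arm trial tables
bcham calibrate target.tsv --seed 1 --out cal/ # fit (b_b2, gamma, Z)
bcham analyze   --seed 1 --pairs 10 --out ana/ # paired benefit/harm grid
```

All outputs are delimited text plus a JSON summary carrying the seed and a
config hash; re-running a command from its logged config reproduces the
outputs byte-for-byte.

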