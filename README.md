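# t2titrate

Simulation and analysis of biomarker-guided corticosteroid titration in
severe asthma.

Many patients with severe asthma are escalated to high-dose inhaled
corticosteroids (ICS) and maintenance oral corticosteroids (OCS) on the
basis of symptoms, yet as many as half lack the type-2 (T2) eosinophilic
airway inflammation that corticosteroids treat. `t2titrate` implements, as
a reusable Python package, the machinery of a 48-week randomised trial that
compares two per-visit dose-adjustment algorithms:

* **Composite T2 biomarker strategy** — FENO (ppb), blood eosinophils
  (cells/µL) and serum periostin (ng/mL) are each banded into a subscore
  s ∈ {0, 1, 2} (FENO <15 / 15–30 / >30; eosinophils <150 / 150–300 / >300;
  periostin <45 / 45–55 / >55), and the composite score is
  round((s₁+s₂+s₃)/3). Composite 0 advises a one-step dose *decrease*,
  1 *maintain*, 2 *increase*; a missing component defaults the advisory to
  maintain.
* **Symptom–risk strategy (control)** — score 2 if a severe exacerbation
  occurred since the last visit or ACQ-7 ≥ 1.5 with ≥ 1-point worsening
  from baseline; 0 if ACQ-7 < 1.0 with no exacerbation; 1 otherwise.

Doses move on a configurable treatment ladder (ICS titrates 200→2000 µg/day
BDP-equivalent, then prednisolone tiers 5→40 mg/day on top), so a decrease
withdraws OCS before ICS. The package is aimed at trial statisticians and
methods researchers who want to study treat-to-target titration designs:
it provides stratified 4:1 permuted-block randomisation, a synthetic-cohort
generator matched to the trial population, adherence/withdrawal behaviour
models, construction of ITT / per-protocol / relaxed-PP / uncontrolled
analysis populations, and the trial's full estimator suite (adjusted
logistic regression with multiple imputation, negative-binomial
exacerbation rates, Cox time-to-first-event, NNT, sensitivity bounds,
Monte Carlo design power).

## Worked example

```python
from t2titrate import (TrialConfig, run_trial, primary_analysis,
                       unadjusted_odds_ratio)
from t2titrate.analysis import exacerbation_models, number_needed_to_treat

ds = run_trial(TrialConfig(), seed=42)      # 301 patients, 240:61 split
est = primary_analysis(ds, "pp", seed=42)   # adjusted per-protocol OR
print(est.point, est.lo, est.hi)
ex = exacerbation_models(ds, "itt")
print(ex["annual_rate"])
```

With seed 42 this simulates 301 patients (1977 attended visits, 391 severe
exacerbations) and prints a per-protocol adjusted odds ratio of **7.47
(95% CI 1.46–38.07)**: patients whose doses were steered by the biomarker
composite were far more likely to end the year on a lower corticosteroid
dose (44.4% vs 9.1% of the control arm), because the symptom-driven control
algorithm rarely advises reductions in a symptomatic population. Annualised
severe-exacerbation rates were 1.42 (biomarker) vs 1.92 (control) events
per patient-year. The same estimators run on printed 2×2 tables:

```python
unadjusted_odds_ratio(31, 70, 1, 19).point      # 8.41
number_needed_to_treat(0.307, 0.050, 101, 20)   # NNT 4
```

A command-line surface wraps the library:

```bash
t2titrate simulate --seed 1 --out sim/        # patients/visits/events CSVs
t2titrate analyze  --in sim/ --population pp --out report.csv
t2titrate power    --n 300 --p1 0.30 --p0 0.10 --dropout 0.2 --reps 5000
t2titrate run      --seed 1 --out run/        # end-to-end with a manifest
```

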