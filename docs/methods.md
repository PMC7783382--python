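# Methods

This note documents the models behind `t2titrate`: what is simulated, what
is estimated, the defaults and why, and what the synthetic data can and
cannot say about a real trial.

## Scoring algorithms

Both per-visit algorithms are deterministic maps to a decision score
in {0, 1, 2} = {decrease, maintain, increase}.

**Composite biomarker score.** Each biomarker is banded with a
closed middle band: value < lower cut → 0, lower ≤ value ≤ upper → 1,
value > upper → 2 (FENO 15/30 ppb, eosinophils 150/300 cells/µL, periostin
45/55 ng/mL). The composite is the rounded average of the subscore sum,
implemented as round-half-up on sum/3. Attainable averages are multiples of
1/3 and never land on .5, so any conventional rounding rule agrees; one
rule is fixed for determinism. If any component is unmeasured the visit is
*defaulted*: composite reads 1 and the advisory is maintain. Eosinophil
inputs below 20 are treated as 10⁹ cells/L and rescaled ×1000 with a
warning, since counts that low are not physiological in cells/µL; the
simulator floors generated counts at 20 cells/µL so canonical units are
unambiguous.

**Symptom–risk score.** Score 2 requires a severe exacerbation since the
last visit *or* (ACQ-7 ≥ 1.5 *and* worsening ≥ 1 point); the conjunction
binds tighter than the disjunction — the only reading consistent with the
score-1 row requiring "no severe exacerbation". Worsening is measured from
the randomisation baseline, per the "baseline score" wording. Score 0
requires ACQ-7 < 1.0 and no exacerbation; everything else is 1.

## Treatment ladder

Doses live on an ordered ladder of (ICS µg/day BDP-equivalent, OCS mg/day)
pairs; OCS tiers only exist above the maximal ICS dose, and adjacent steps
differ in exactly one dose. Advisories move exactly one step; at the
boundaries the state is returned unchanged with an `at_floor`/`at_ceiling`
flag. The protocol's exact step list is not public; the default —
ICS {200, 500, 800, 1000, 2000} then OCS {5, 10, 15, 20, 30, 40} on ICS
2000 — is a documented stand-in chosen so that the typical baseline
(ICS 2000) sits one step above 1000 µg, reproducing the observed median
reduction of 1000 µg among reducers, and so that step-down withdraws OCS
before ICS (standard clinical practice). The ladder, like the band cuts,
is overridable through the YAML config.

## Synthetic cohort

The generator emulates the trial population's printed baseline summaries.
Biomarkers use log-normal margins for FENO (median 21 ppb, IQR 13–29) and
eosinophils (median 0.20×10⁹/L, IQR 0.11–0.32) — parameterised directly
from median/IQR — and a normal margin for periostin (mean 52.8, SD 15.7),
joined by a Gaussian copula with pairwise correlation 0.3 (the papers
report only marginals; 0.3 is a calibration that reproduces the printed
baseline composite-score distribution of roughly 23% / 56% / 20%).
Enrolment rejects FENO ≥ 45 ppb, mimicking the screen that enriched the
trial for a biomarker-low population. Because that screen also trims the
correlated upper tails, and because the latent low class (below) sits
wholly below each median, the raw log-means are back-corrected
analytically (Mills-ratio shift for the screen, mixture-quantile shift for
the low class) so the *post-screen* sample medians hit their targets.

A latent **T2-low class** (default 5%, the prevalence observed among
completers) has biomarker set-points pinned strictly below every lower cut
and insensitive to corticosteroid dose — these are the patients the design
hopes to step down to the ladder floor. All other patients' set-points
rebound multiplicatively when corticosteroids are withdrawn:
one ladder step down multiplies each set-point by `rebound` (default 1.15;
no magnitude is published, so this is a free, documented parameter), and
correlated log-normal visit noise (SD 0.30 on the log scale, sharing the
baseline copula — T2 flares move the three biomarkers together) is applied
on top. ACQ-7 follows an AR(1) around its baseline with a +0.6 bump per
interval exacerbation. Covariates (age, sex, smoking, centre, rescue
courses, baseline doses, AQLQ, FEV₁%) match the printed Table of baseline
characteristics; 36% start on maintenance OCS (median tier 10 mg) and ICS
is concentrated at 2000 µg/day.

**Exacerbations** are Poisson per 8-week interval with
log rate = log(1.15) + 0.25·composite + log(frailty) + log(weeks/52),
where frailty is gamma with mean 1 and variance 0.5 across patients
(negative-binomial margins). The base rate and score coefficient are
calibrated so the ITT annualised rate falls in the printed 1.4–1.7
events/patient-year band and a raised composite score carries excess risk.

## Trial conduct

Randomisation is stratified (baseline ACQ-7 ≥ 1.5 × ≥ 2 rescue-steroid
courses) permuted blocks of ten at 4:1; terminal blocks are truncated
permuted blocks (how the real trial closed incomplete blocks is unstated).
Visits run every 8 weeks from 0 to 48; advisories are issued at weeks 0–40
and week 48 is assessment only. Masking is structural: every patient
receives the same message schedule, with a default-maintain message
standing in for the inactive algorithm; it is recorded but never moves a
dose. An exacerbation still under management at a visit (event within
2 weeks, configurable) defers any dose change to the next visit.

**Adherence** is per-advisory Bernoulli with direction-specific
probabilities, a mean-preserving linear decay across the six advisory
visits (advice-following declined as the study progressed), centre-level
shifts (SD 0.05 across 12 centres, reflecting wide between-centre
variation), and an absorbing latent class (default 55%) that always
refuses an increase that would *initiate* maintenance OCS. Defaults
(maintain 0.954; voluntary change-follow 0.75 biomarker / 0.67 control;
per-visit biomarker missingness 0.10) are calibrated to the printed
advisory accounting: with them, long-run simulated marginals are ≈ 85% of
all biomarker-arm advisories followed and ≈ 65% of change advisories
(≈ 58% control), matching the trial's 1041/1224, 273/419 and 77/133.
Maintain-advisory adherence 0.954 is derived from those counts:
(1041−273)/(1224−419). Withdrawal is a per-visit hazard of 0.0192,
giving ≈ 11% cumulative dropout (32/301 in the trial); withdrawn patients
keep their recorded visits, so they remain ITT-eligible.

## Analysis populations and estimators

ITT = attended ≥ 1 follow-up visit. A *deviation* is an unfollowed,
undeferred advisory or a missed scheduled visit, except that an unfollowed
decrease while already at the ladder floor is exempt, and low-cortisol
patients are exempt entirely. PP = zero deviations; relaxed PP(k) ≤ k;
uncontrolled = ITT with baseline ACQ-7 ≥ 1.5. These nest by construction
and the nesting is asserted in tests on every simulated dataset.

The primary outcome — ladder step at week 48 strictly below baseline,
which coincides with "OCS lower, or OCS equal and ICS lower" — is analysed
by logistic regression adjusted for age, sex, smoking status, treatment
centre, rescue-steroid use (≥ 2 courses) and baseline ACQ-7 ≥ 1.5. Missing
outcomes are multiply imputed by chained equations (statsmodels MICE;
default m = 20 imputations after 10 burn-in cycles — the trial reports the
method but not the counts), with the imputation model additionally
carrying the baseline-to-first-visit dose change; estimates pool by
Rubin's rules. With no missing outcomes the complete-case fit is returned
unchanged. If the complete-case fit separates, a profile-likelihood
interval for the treatment coefficient is computed by offset-refitting and
likelihood-ratio inversion; in small or degenerate fits the centre dummies
are dropped with a flag. Best-/worst-case sensitivity bounds refit after
setting all withdrawals' outcomes to reduced / not reduced.

Unadjusted 2×2 odds ratios use the cross-product with a Woolf log-scale
interval and Haldane–Anscombe 0.5 correction (flagged) on zero cells.
NNT is ⌈1/risk difference⌉ with a Newcombe hybrid-score interval on the
risk difference, reciprocated and rounded; the trial does not state its
NNT interval method, so Newcombe is the documented choice here.
Exacerbation and hospitalisation counts use negative-binomial regression
with log person-years offset (Poisson fallback, flagged, if the NB fit
fails); time to first exacerbation uses a lightly penalised Cox model
(lifelines, penalizer 0.01 for stability at trial-sized n). Continuous
secondary outcomes (ACQ-7, AQLQ, FEV₁%, log-FENO, log-eosinophils,
periostin, doses) use adjusted linear models further conditioned on the
baseline measurement. Annualised per-arm rates are exact events over
person-years, so rate × exposure reproduces the count.

## Design power

The power engine simulates the design point directly: 300 patients 4:1,
uniform random 20% dropout (design-stage convention; the informative
dropout structure lives in the conduct simulator, not here), binary
outcomes at 30% vs 10%, pooled two-proportion z-test at two-sided 5%
(an unadjusted logistic Wald variant is available). The estimate carries a
binomial Monte-Carlo SE and is checked against the closed-form
normal-approximation power, which is 0.87 at the design point.

## Numerical and design choices

* Seeds: every stochastic routine takes an explicit seed or generator;
  end-to-end runs are byte-reproducible and the CLI writes a manifest with
  checksums. One exception is documented: statsmodels' MICE draws from the
  global numpy RNG, which `primary_analysis` seeds explicitly.
* Test problem sizes: marginal-distribution checks use n = 5000 cohorts;
  calibration checks average four n = 301 trials; the null-calibration
  suite uses 500 replicates at n = 300. These sizes put Monte-Carlo error
  well inside the asserted tolerances while keeping the suite quick.
* Degenerate inputs: zero-variance configs produce identical patients;
  empty cohorts, empty randomisation lists, all-withdrawn datasets and
  empty 2×2 margins return empty/flagged results rather than raising.

## What the synthetic data do and do not show

The generator reproduces the trial's *marginal* structure (baseline
distributions, advisory mix, adherence and withdrawal rates, exacerbation
rates) and the qualitative mechanisms (biomarker rebound on dose
withdrawal, OCS refusal, deferral). It does not model: informative
(health-driven) withdrawal; within-patient correlation between adherence
and unmeasured severity; FEV₁ decline mechanics (FEV₁ is a noisy covariate
only); seasonality of exacerbations; or centre-level case-mix differences
beyond adherence shifts. Consequently, passing tests demonstrate that the
estimators are correctly implemented and calibrated under the stated
generating model — not that the trial's covariate-adjusted effect
estimates would be reproduced on the real cohort, whose patient-level data
are not public. Simulated effect sizes (e.g. the per-protocol odds ratio)
depend on the behaviour model's parameters and should be read as
internally consistent, not as estimates of the clinical effect.
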