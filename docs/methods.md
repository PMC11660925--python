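# Methods

`msphase` analyses longitudinal multiple-sclerosis registry data in which a
patient diagnosed with relapsing-remitting MS (RRMS) may later receive a
physician diagnosis of secondary progressive MS (SPMS), and the SPMS phase is
further split by recent relapse activity into relapsing (rSPMS) and
non-relapsing (nrSPMS) states.  This note records the models, the conventions
behind every tunable choice, and what the synthetic generators do and do not
emulate.

## Daily phenotype classification

The phenotype on follow-up day *t* is

* **RRMS** if no SPMS diagnosis exists or *t* precedes it;
* **rSPMS** if an SPMS diagnosis is in effect and at least one relapse falls
  in the retrospective window (*t* − *W*, *t*], with *W* = 730 days;
* **nrSPMS** otherwise.

Conventions the definition leaves open, fixed here:

* The window is **half-open on the left and closed on the right**: a relapse
  on the assessed day itself makes that day rSPMS, and an isolated relapse at
  day *r* keeps the patient rSPMS through day *r* + 729, so the first
  nrSPMS day is *r* + 730.  With a single pre-diagnosis relapse 100 days
  before the SPMS diagnosis this puts the first nrSPMS day at day 630 of the
  SPMS phase, which is the worked example the test suite pins down.
* Relapses recorded **before** the SPMS diagnosis count toward the window
  (so a patient can enter the SPMS phase already relapsing), but they do
  **not** count toward the "cumulative relapses since RRMS diagnosis"
  covariate, which starts at the diagnosis day by its own definition.
* Interval classification is computed as the union of relapse cover
  intervals [max(*r*, dx), *r* + *W* − 1] in O(#relapses), and is tested to
  agree with a brute-force day-by-day evaluation.

All dates are integer day offsets from 2000-01-01; durations convert to
years by /365.25.  A 1-year activity window was deliberately not provided:
registry visit gaps exceed a year, which is the rationale for the 2-year
window this package implements.

## Panel construction

The multi-state model consumes panel observations: (time, state, covariates)
at each registry visit.  The default schedule is the patient's EDSS visit
days plus the SPMS diagnosis day — visits are when the registry actually
observes the patient.  Covariates at day *t*:

| covariate | definition | units |
|---|---|---|
| `sex_female` | indicator | — |
| `age` | age at onset + (t − onset)/365.25 | years |
| `hedmt_years`, `medmt_years` | cumulative time on high-/moderate-efficacy DMTs up to t | years |
| `edss` | last EDSS at or before t (LOCF); before the first visit, the first value within 365 days ahead; otherwise the patient is flagged and excluded from the Markov fit | 0–10 |
| `dx_year` | calendar year of RRMS diagnosis (continuous) | years |
| `cum_relapses` | relapses in (dx, t] | count |
| `dx_duration` | onset-to-diagnosis interval | years |

High-efficacy DMTs: alemtuzumab, cladribine, daclizumab, fingolimod,
natalizumab, ocrelizumab, ofatumumab, ozanimod, rituximab, siponimod.
Moderate-efficacy: dimethyl fumarate, diroximel fumarate, glatiramer
acetate, the interferon-beta family (matched by substring, so spelling
variants classify correctly) and teriflunomide.  Unknown drug names are kept
but contribute to neither exposure; registries contain non-DMT entries.
Episodes of one patient overlapping within an efficacy class are merged on
load; overlapping episodes of *different* classes accrue both exposures in
parallel, since nothing in the definition of the two covariates makes them
exclusive.  Death enters the panel as an exactly observed final record.

## The multi-state Markov model

Four states — RRMS (1), nrSPMS (2), rSPMS (3), Death (4, absorbing) — with
allowed transitions 1→2, 1→3, 2→3, 3→2 and death from every transient state.
RRMS is never re-entered (the irreversibility of the SPMS assignment); the
two SPMS states are mutually reachable.  Intensities are proportional:

    q_rs(z) = q0_rs · exp(β_rs · z_rs)

with a transition-specific covariate subset z_rs: the full eight covariates
on the two RRMS exit transitions, {sex, age, both DMT exposures, EDSS} on
the SPMS↔SPMS transitions, and {age, sex} on the death transitions.  Time is
measured in years, so intensities and hazard ratios are per-year.

**Likelihood.** For consecutive observations (t_i, s_i) → (t_j, s_j) the
contribution is entry (s_i, s_j) of exp(Q(z_i)·(t_j − t_i)); covariates are
piecewise-constant at the interval's **left endpoint**, the standard
panel-data convention.  An exactly observed death at t_d contributes the
density Σ_s P(t_i, t_d)[s_i, s]·q_{s,Death}(z_i) over transient s.
Non-death censoring contributes nothing beyond the last observed panel pair.
An observed transition with probability zero yields −∞ with a diagnostic
naming the offending pair.

**Numerics.** Matrix exponentials use scaling-and-squaring with the Padé-13
approximant, vectorized over stacks of interval matrices (the likelihood
needs tens of thousands of 4×4 exponentials per evaluation); accuracy is
checked against `scipy.linalg.expm` to 1e-12, and no eigendecomposition is
assumed, so defective intensity matrices are safe.  Maximization is bounded
quasi-Newton (L-BFGS-B) with box bounds log q0 ∈ [−20, 5] and β ∈ [−10, 10],
which prevent overflow excursions without binding at any realistic optimum;
baseline intensities initialize at crude rates (observed jumps per
person-year at risk) and coefficients at zero.  The covariance matrix is the
inverse of the central-difference observed information (step 1e-4·max(1,|θ|),
symmetrized); when a flat direction (for example an allowed transition never
observed) leaves the numeric information indefinite, the covariance is
projected onto the PSD cone with a warning.  Wald 95% intervals use
z = 1.959964.  Covariates are used uncentered; centering is available purely
for conditioning and does not change reported hazard ratios.

**Predictions.** Transition-probability matrices at 5/10/15 years come from
the fitted model; 95% CIs are the 2.5/97.5 percentiles of (by default) 100
draws from the multivariate normal asymptotic distribution of the estimates,
each mapped through the same probability computation.  The draws perturb the
covariate coefficients together with the log intensities — they are one
parameter vector with one joint covariance, and drawing only the intensities
would understate the uncertainty.  Goodness of fit compares observed state
prevalence (state carried forward between visits, death persisting, counts
restricted to patients under observation) with the average of model
transition-probability rows from each patient's first observation, both
renormalized over the same risk set.

## Survival estimators

* **Aalen–Johansen** cumulative incidence is computed directly (risk sets
  support late entry; conservation surv + ΣCIF = 1 holds identically by
  construction) and is cross-checked in the tests against the complement of
  an independently computed Kaplan–Meier curve in the single-event case.
* **Kaplan–Meier** wraps lifelines' product-limit fitter.
* **Cox** models use the Breslow tie rule (statsmodels `PHReg`) with late
  entry.  Disability-milestone analyses follow patients from MS onset to the
  first EDSS observation ≥ 3, 4 or 6 — an *unconfirmed* first crossing, no
  sustained-progression requirement — censored at SPMS diagnosis or end of
  follow-up, adjusted for age at onset and sex.  Ties everywhere resolve
  events before censorings.  A Schoenfeld-residual trend test is provided as
  the proportional-hazards diagnostic.
* **Poisson ARR** uses a log link with log-exposure offset and HC0 sandwich
  variance; the intercept-only model reproduces total events / total
  person-years exactly.  An all-zero count vector returns rate 0 with the
  exact Poisson 97.5% upper bound rather than a failed fit.
* **GEE ARR trajectories** count relapses per 1-year age bin during the
  relapsing-remitting phase — which ends 730 days before the SPMS diagnosis
  for converters, so the relapses that *define* the subtypes are excluded —
  and model them with a Poisson GEE (log link, offset, patient clusters).
  The default working correlation is unstructured, which requires age bins
  aligned across patients; on the unbalanced bins of any realistic registry
  it falls back to exchangeable with a logged warning.  Robust sandwich
  inference is used either way.  The age trend enters as a polynomial of
  configurable degree (default linear — the simplest defensible choice, and
  a documented knob).

## Synthetic data

Two generators with deliberately different relationships to the inferential
model:

**Mechanistic registry simulator** (`simulate_cohort`): per patient, sex
(70% female), age at onset ~ N(34.1, 9.2²) truncated at 18, onset uniform
over an 11-year accrual window, diagnosis delay lognormal (median 1 year),
administrative horizon at day 8280 (~22.7 years).  Relapses are an
inhomogeneous Poisson process simulated by thinning against a per-patient
dominating rate (exact for arbitrary log-linear modifiers): base 0.45/year,
declining 2%/year of age, +15% for women, ×4 in the 2 years before RRMS
diagnosis (diagnosis is triggered by activity; this reproduces a ~1.7–1.8
pre-diagnosis ARR), damped on treatment (high-efficacy ×e^{−1.2},
moderate ×e^{−0.5}) and reduced to 25% after latent SPMS onset (a free knob:
no published value for the residual post-progression relapse rate exists).
Latent SPMS onset follows a hazard log-linear in age (+4%/year) and current
EDSS (+25%/point) with baseline 0.02/year, and the *recorded* diagnosis lags
it by an exponential delay (mean 2 years), reflecting documented diagnostic
delay; EDSS is a non-decreasing 0.5-step jump process (expected drift
0.15/year before latent onset, 0.45 after, 30% chance of a +0.5 step per
relapse) observed at visits ~365 ± 90 days apart; death
(0.02/year at age 65, +9%/year) and emigration (0.003/year) compete with the
administrative censor.  Within an inter-visit segment the SPMS/death hazards
are frozen at their segment-start values — a first-order approximation that
matches how the covariates themselves are observed.  These trajectories
violate the Markov property (latent states, delays, duration effects), which
is the point: they exercise classification, attrition handling and
goodness-of-fit rather than flattering the estimator.

**Exact CTMC simulator** (`simulate_panel_ctmc`): competing exponential
clocks under the model's own intensity matrices, piecewise-constant
covariates, states recorded only at schedule days, absorption recorded
exactly.  Because generator and model coincide, parameter-recovery tests are
sharp: the acceptance suite fits the four-state structure to 1000 patients
observed annually over 20 years (with a binary and a continuous covariate on
three transitions, 11 parameters) and checks every estimate within 3
standard errors, plus pooled 95% Wald coverage across 50 replicates of 150
patients (intensities only) against the [88%, 100%] band.  Passing these
shows the estimator is correct *under its own assumptions*; it does not show
the Markov model is adequate for real registry courses — the
observed-vs-expected prevalence comparison on mechanistic data is the tool
for that question.

## Problem sizes and defaults

Simulation-based checks use 150–2000 patients: large enough that 3-standard-
error bands are meaningfully tight, small enough to keep each check in
seconds to a few minutes.  The pipeline's quick presets use the reduced
per-transition covariate sets and a capped optimizer iteration count;
published-scale analyses should use `covariates="full"` and the default
`maxiter=500`.  The significance convention is two-sided p < 0.05 with no
multiplicity adjustment, and the pipeline report says so.

## Known limitations

* No MRI activity: the rSPMS/nrSPMS split uses relapses only, so "active"
  disease visible only on imaging is invisible here by design.
* No hidden-Markov extension: state misclassification (for example a missed
  relapse silently mislabelling rSPMS as nrSPMS) is not modelled.
* Sojourn times are exponential given covariates; duration-in-state effects
  are not representable.
* The EDSS process carries forward indefinitely between visits; long gaps
  therefore understate disability drift.
* The Cox milestone analysis uses unconfirmed first crossings; confirmed-
  progression definitions would shift milestone times later.
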