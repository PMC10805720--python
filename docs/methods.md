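# Methods

This note documents the models, rules and design choices implemented in
`sepsis_impact`, what the synthetic generator does and does not emulate, and
the numerical conventions used throughout.

## Sepsis-3 electronic phenotype

**Suspicion of infection.** A blood-culture order paired with a qualifying
antibiotic course: if the culture is ordered first, an IV non-prophylactic
antibiotic order must follow within 72 h; if the antibiotic order comes
first, a culture must follow within 24 h. The qualifying course requires at
least four *consecutive calendar days*, each with ≥ 1 non-prophylactic IV
administration, starting at the first qualifying dose; a course truncated by
death or discharge before day 4 still qualifies (surveillance-style
exception — septic cohorts plainly contain early deaths). Whether a drug is
IV and non-prophylactic is an explicit token in the event vocabulary
(`units` column: `iv-nonprophylactic` / `iv-prophylactic` / `po`); no
drug-name heuristics are applied. Orders anchor the 72 h/24 h pairing;
administrations drive the 4-day rule.

**Suspicion time** is the earlier member of the earliest qualifying
(culture, antibiotic-order) pair. All window boundaries are closed at
minute resolution: "within 72 h" means ≤ 72:00 exactly.

**Organ dysfunction.** SOFA is computed with the standard published
sub-score thresholds for respiration (PaO₂/FiO₂), coagulation (platelets),
liver (bilirubin), cardiovascular (MAP and vasopressor dose), CNS (GCS) and
renal (creatinine). Each sub-score at time *t* uses the worst qualifying
measurement in `(t − 24 h, t]` (lookback configurable); a channel with no
measurement scores 0 (missing-as-normal). The respiration sub-score applies
the 400/300/200/100 cut-points without a ventilatory-support qualifier, as
is common in electronic implementations; the event stream carries no
ventilation channel. Renal scoring uses creatinine only (no urine output).

**Baseline SOFA** is the minimum SOFA over `[suspicion − 48 h, suspicion]`,
evaluated at the times of SOFA-relevant measurements, and 0 when no prior
data exist (community-presentation assumption). Organ dysfunction requires
max SOFA over `[suspicion − 48 h, suspicion + 24 h]` minus baseline ≥ 2.

**Inclusion.** Sepsis onset = suspicion time. Included encounters are
adults (≥ 18 y) with onset within 12 h of ED arrival and no comfort-care
order at or before onset. Exclusion reasons are recorded as `no_sepsis`,
`onset_after_12h`, `age_under_18`, `comfort_care_before_onset` (checked in
that order).

## Outcomes

- **In-hospital mortality**: disposition of death before departure.
- **72-h ΔSOFA**: worst SOFA total in `(onset, onset + 72 h]` minus the
  total at onset. The worst-minus-onset reading is used (rather than
  value-at-72-h minus onset) because the change is intended as a measure of
  accrued organ injury; patients dying within 72 h contribute their observed
  maximum. The result is never negative.
- **ICU-free days**: 30 − (total ICU days, hours rounded up), forced to 0
  for patients who die inside an ICU interval or accumulate ≥ 30 ICU days,
  clamped to [0, 30]. ICU intervals come from unit-transfer events; an
  open interval closes at departure. The "≥ 30 days ⇒ 0" reading resolves
  an ambiguity between "longer than 30" and "more than 29" phrasings of the
  rule; the boundary case (exactly 30 ICU days) scores 0 either way under
  integer day counting.
- **Bundle compliance** (per element, each on its own window):
  culture-before-antibiotics (first culture order at/before first
  antibiotic administration); antibiotics within `[onset − 24 h, onset + 3 h]`;
  initial lactate within `[onset − 6 h, onset + 3 h]`; repeat lactate within
  6 h of the first lactate, applicable only when the first lactate exceeds
  2 mmol/L; vasoactives within 6 h of septic-shock presentation (applicable
  only with shock); ≥ 30 mL/kg crystalloid within 3 h of shock/hypotension
  presentation (applicable only with shock or hypotension). Shock/
  hypotension presentation is the first time at/after onset with MAP < 65
  mmHg, SBP < 90 mmHg, or lactate ≥ 4 mmol/L (thresholds are module
  constants). Composite compliance requires every applicable, determinate
  element to be met; an applicable fluid element with missing weight is
  indeterminate and drops out of the composite denominator rather than
  counting as failure.
- **Time to antibiotics**: first antibiotic administration minus arrival, in
  fractional hours; absent when no antibiotics were given.
- **Acknowledgement category**: the acknowledgement of the encounter's first
  alert (`no_infection`, `workup`, `notify_md`, `none`), or `no_alert`.

## Monthly aggregation

Outcomes are aggregated at monthly resolution to damp encounter-level
noise. Each month contributes the mean outcome over included septic
encounters arriving that month, the septic count `n`, and covariates: total
ED volume over all comers; percent male, mean age, mean baseline SOFA, mean
Elixhauser, COVID positivity and site mix averaged over that month's septic
encounters; and calendar-quarter dummies for season. "Local trends" are
carried by the ED-volume covariate. The go-live month is assigned wholly to
the post period (the study calendar's December 2022 split month becomes a
post month, giving 23 pre and 5 post months). Months with zero septic
encounters are dropped with a warning; zero-variance covariate columns are
flagged because the regression cannot identify their coefficients.

The drift check compares observed feature medians to closed control-limit
intervals `[lower, upper]` (e.g., training-cohort quantiles); a median
exactly at a limit is in control.

## Causal-impact model

The monthly outcome is modeled as a local linear trend plus a static
regression on contemporaneous covariates, with Gaussian observation noise.
Rates are modeled on the raw scale (a documented limitation of this model
family: no binomial link, so intervals near 0 or 1 can be slightly
miscalibrated). Outcome and covariates are centered and scaled using
**pre-period statistics only**, preventing post-period leakage, and all
outputs are back-transformed to original units.

**Priors** (on the standardized scale) follow the weakly-informative
conventions of the structural-time-series causal-impact literature:

| parameter | prior | default |
| --- | --- | --- |
| σ_level | inverse-gamma, prior guess 0.01 × sd(y), effective prior sample size 32 | `prior_level_sd_scale = 0.01` |
| σ_slope | same form | `prior_slope_sd_scale = 0.01` |
| σ_obs | inverse-gamma, df 0.01, scale from an expected R² of 0.5 | |
| inclusion | Bernoulli(expected_model_size / K) per covariate | `expected_model_size = 1` |
| β (slab) | Zellner-style N(0, σ² Ω⁻¹), Ω = (g/n)(½ XᵀX + ½ diag XᵀX) | `g = 0.01` effective prior observations |

Setting both state SD scales to zero pins the trend at zero and reduces the
model to conjugate Bayesian regression (used as a closed-form cross-check).

**Sampler.** A Gibbs sweep alternates (a) forward-filtering
backward-sampling of the 2-dimensional state path given the de-regressed
series, with a diffuse initial state centered at the first observation;
(b) conjugate inverse-gamma updates of the two innovation variances;
(c) a collapsed single-site Gibbs update of the inclusion indicators
(integrating out β and σ_obs), followed by conjugate draws of σ_obs² and
the included coefficients. Defaults: 1000 retained draws after 100 burn-in
sweeps ("1000 MCMC samples" read as retained posterior draws), fully
reproducible under a fixed seed. Degenerate 2×2 covariances in the backward
pass are handled by a zero-safe Cholesky; sums of squares are floored at
1e-12.

**Counterfactual and effects.** For each retained draw the trend is
iterated forward from that draw's final state with its sampled innovation
SDs; the regression term and observation noise are added, giving one
counterfactual trajectory per draw. Per draw, the absolute effect is the
observed post-period mean minus the counterfactual mean, the relative
effect divides by the counterfactual mean, and the cumulative effect is the
sum of pointwise effects (identically H × absolute effect). Intervals are
central posterior quantiles. The one-sided tail-area probability is the
posterior mass of cumulative effects whose sign opposes the median effect,
with ties at zero split evenly and a +0.5/(R+1) continuity adjustment so it
stays inside (0, 1); an exact null yields 0.5. The cumulative-effect
framing is the default; an average-effect variant follows trivially since
the two differ only by the factor H.

**Reporting.** The pipeline's summary table mirrors an impact table:
encounter-weighted pre-period value, expected post value with 95% interval,
actual post value, and a significance flag set when the observed value
falls outside the counterfactual interval. No multiplicity correction is
applied across outcomes.

## Association model and descriptive tests

Time-to-antibiotics (hours) is regressed by OLS on age, a male indicator,
Elixhauser index, baseline SOFA, monthly ED volume in thousands, and
acknowledgement-category indicators with *no acknowledgement* as the
reference level, restricted to alerted septic encounters with an observed
antibiotic administration. Inference is classical (t distribution on
residual df); no robust or clustered errors. Rank-deficient designs raise
an error naming the collinear columns. Kruskal–Wallis uses the tie-corrected
H with a χ²(k−1) approximation; the chi-squared test is Pearson's without
continuity correction, rejecting tables with a zero margin. scipy supplies
distribution functions only; the statistics themselves are computed
directly.

## Synthetic generator: what it emulates, and what it does not

The generator is intent-first: for each septic encounter it draws the
intended label, mortality, compliance, acknowledgement and shock status,
then emits an event stream realizing that intent through textbook
qualifying patterns (early culture, paired antibiotic order, daily IV
course, SOFA-relevant labs inverted from target sub-score trajectories).
Defaults encode the study conditions: two sites × 4167 visits/site/month
(~100k/yr) over 2021-01-01…2023-04-30 with go-live 2022-12-07; septic
prevalence 2.69% and a 1.94% comfort-care exclusion rate, calibrated so the
expected included septic count is ≈ 6217; pre-period septic mortality 10.3%
with a −1.9-point step at go-live; composite compliance 48.3% with a
+5.0-point step; mean 72-h ΔSOFA 3.71 (distributed as 2 + Poisson, floored
at 3 for shock patients whose bundled vasopressors force a cardiovascular
sub-score of 3); ICU transfer 32.6%; alert sensitivity 80% and PPV 20.1%;
acknowledgement mix (no-infection 0.15, workup 0.24, notify-MD 0.551,
none 0.059) — only the "over half notify-MD" and 5.9%-unacknowledged
figures are externally fixed, the remaining mass is split plausibly and
exposed as configuration; lockouts 8 h (no-infection), 12 h (workup,
notify-MD), none for unacknowledged alerts. Antibiotic timing for
non-compliant encounters follows a linear model whose acknowledgement
offsets default to the published association signs (notify-MD ≈ −20 h
versus unacknowledged), so the association analysis is recoverable;
compliant encounters receive antibiotics inside the 3-h window regardless
of acknowledgement, which attenuates but does not erase the association.

Deliberate simplifications: timestamps at minute resolution, one time zone,
no daylight-saving handling; non-septic encounters carry sparse streams
(vitals, occasional lactate, occasional unpaired cultures or oral
antibiotics) sufficient to exercise the phenotyper's negative path; the
composite-compliance probability is the calibrated quantity, so individual
element rates are internally consistent but not separately matched to any
external element-level figures; non-shock septic lactates are capped below
the 4 mmol/L shock threshold so shock-only bundle elements stay
inapplicable for them; the alert risk-score trajectory itself is not
simulated, only its alert/acknowledgement footprint. Mortality is
conditionally independent of covariates given period, so covariate
coefficients in the causal model are truly null under the generator — tests
passing on this data demonstrate correctness of the machinery and
calibration under the stated conditions, not performance on real EHR data
with informative missingness, coding drift, or confounded covariates.

## Problem sizes used in tests

The test suite keeps the full study calendar but scales volume down
(typically 150 visits/site/month with prevalence 0.30, ≈ 110 septic
encounters/month) so the whole suite runs in well under two minutes. The
causal-core calibration checks run 25 seeded replicates of a 28-month,
8-covariate series with 1000 retained draws each: a no-effect world (the
95% cumulative-effect interval may exclude zero in at most ~7% of
replicates) and a world with a −2-percentage-point mortality step (the 95%
absolute-effect interval must cover it in ≥ 80%). The conjugate closed form
is checked with the trend pinned at zero. Phenotype adjudication is
compared against an independent brute-force window-enumeration oracle on
500 generated encounters plus hand-seeded boundary cases (exact 72 h/24 h
pairs, onset exactly at 12 h, truncated antibiotic courses, comfort-care
and age exclusions), and SOFA totals against an exhaustive 5⁵ grid of
component values.

## Known limitations

- Gaussian observation model for rates (no binomial likelihood).
- No seasonal state component; season enters only as quarter dummies in the
  regression.
- Static regression coefficients (no dynamic regression), single outcome per
  fit, no model averaging across trend specifications.
- The spike-and-slab update is single-site; with strongly collinear
  covariates mixing over inclusion patterns can be slow (the slab's
  half-diagonal Ω guards the linear algebra but not the mixing).
- The generator's acknowledgement-conditional antibiotic timing is a
  convenience construction; it encodes the direction and rough magnitude of
  the published association, not a mechanistic model of nurse-physician
  communication.
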