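# Methods

## Design model

A study cohort is 13 subjects, ten followed for 30 days and three for 29.
Each day has three survey slots (morning 10:00–12:00, afternoon 13:00–15:00,
evening 17:00–19:00, each with a 2-hour response window); each completed
session answers 3 of the 9 PHQ-9 items, drawn uniformly **without
replacement within a session and independently across sessions**. Across a
day an item may therefore be asked up to three times or not at all. Prompts
may be reverse-worded; a reversed prompt's raw answer r is mapped to the
canonical scale as 3 − r before any computation. Sessions are keyed by
(subject, day, slot); timestamps are carried for provenance but play no role
in estimation. Missingness is session-level: a session is either completed
(all three items answered) or absent, which matches an all-or-nothing survey
screen; item-level skips are not modelled.

## Daily score estimator

All estimation is strictly within-subject. For each item the daily mean of
its canonical responses is the unit of history; within-day repeats collapse
to that mean and contribute **one** difference term. The alternative —
summing one difference per response — would break both the 0–27 range and
the exact-recovery property whenever an item repeats within a day, so the
per-item form is used deliberately.

- *Prediction*: trailing mean of the item's daily means over the 14 days
  strictly before the target day. The current day is never used. During the
  first two weeks the window simply covers whatever prior days exist; those
  days are flagged `burn_in` rather than dropped.
- *Cold-start fallback* when an item has no window history: (1) the
  subject's all-time prior mean for that item, (2) the subject's prior mean
  over all items, (3) the scale midpoint 1.5. All three stay within-subject.
- *Estimate*: prediction plus Σ(observed daily mean − prediction) over
  observed items, computed as "observed items replace their predictions",
  which makes exact recovery (all 9 items observed ⇒ plain PHQ-9 sum) hold
  to machine precision rather than to floating-point cancellation error.
- *Variance*: sum over all nine items of the sample variance (denominator
  n − 1) of the item's window daily means; an item with fewer than two
  window days contributes 0. Summing over all items — not just the observed
  ones — is the interpretation adopted here: the CI describes the predicted
  total.
- *CI*: prediction ± z·√variance with z the standard normal quantile
  (1.959964 at 95%), truncated to [0, 27]. The interval is centred on the
  **prediction**, and a day is flagged `high`/`low` when the **estimate**
  exits it: the question asked is whether today's observations deviate from
  what past variation predicted.
- *Suicidality*: any canonical response to item 9 of 2 or 3 on a given day
  flags that day, regardless of the daily mean.

The naïve baseline for a day with m ≥ 1 distinct observed items is
(9/m)·Σ observed daily means, absent when m = 0.

## Synthetic cohort generator

No generative model of symptom dynamics is prescribed by the design, so the
generator uses the simplest structure that produces the features the
analysis depends on (day-to-day fluctuation, smooth multi-day trends, an
app-above-clinic reporting gap, slot-dependent adherence):

- **Latent severity**: per subject, a mean-reverting AR(1) on the 0–27
  total-score scale. L(1) ~ N(μ, σ₀²); L(d+1) = μ + φ(L(d) − μ) + ε,
  ε ~ N(0, σ²), clamped to [0, 27]. Defaults: μ = 11.64 (the 8.62 clinic
  baseline plus the 3.02 reporting bias, since the latent scale is
  app-referenced), σ₀ = 4.56, φ = 0.8, σ = 1.5. φ and σ are free parameters
  chosen to give severity a ~5-day correlation time and ±2.5-point
  stationary day-to-day spread — visible fluctuation without swamping the
  between-subject differences.
- **Item responses**: item i's latent share is L·w_i with uniform loadings
  w_i = 1/9; the ordinal response is that share plus N(0, 0.5) momentary
  noise, rounded half-to-even and clamped to 0–3. The noise SD of half a
  Likert step acts as dither: it makes the expected rounded response nearly
  linear in the latent share, so means and differences survive the ordinal
  quantization. Rounding is half-to-even (so a noise-free per-item latent of
  1.5 maps to 2) — stated because it affects small worked examples.
- **Adherence**: session completion is Bernoulli with slot probabilities
  0.755/0.842/0.755 shifted per subject by a N(0, 0.5) logit offset,
  putting typical per-subject completion between roughly 0.60 and 0.93 —
  variable but uniformly high.
- **Reverse wording**: each prompt is reversed with probability 0.2; the
  stored raw value is the reflected one, exercising canonicalization.
- **Clinic scores**: the same noisy ordinal response process applied to
  L − 3.02 (clamped), once at day 1 and once at the final day, including an
  item-9 value for the suicidality cross-tab. Running the *identical*
  response process on a shifted latent makes the 3.02-point app-vs-clinic
  gap a recoverable parameter; generating clinic items noise-free would
  instead quantize every uniform-loading total to a multiple of 9 and
  destroy that recoverability.

What the generator does **not** emulate: treatment effects, dropout, survey
fatigue or early-study adherence dips, circadian within-day symptom
structure, item-specific response styles (loadings are uniform), and
within-day dependence of repeated answers to the same item (each response is
drawn independently). Passing tests therefore show that the pipeline
recovers the quantities this structure encodes, not that real EMA data meet
these assumptions.

## Adherence analysis

A session counts as completed iff at least one response record exists for
it; the generator never produces partial sessions. Rates are reported as
100·completed/scheduled at cohort, slot, subject, and day granularity. The
time-of-day comparison is a one-way ANOVA across slots on per-subject
slot-level completion rates (13 × 3 cells), making subjects the replication
unit. Its type-I behaviour is checked in a null regime with equal slot
probabilities and **no** subject-level adherence offsets: with shared
offsets the three slot columns become correlated repeated measures and the
classical one-way F is conservative by construction, so the iid null is the
regime where the 5% level is meaningful.

## App-vs-clinic comparison

Per subject: the mean daily **estimate** over all study days (burn-in
included by default; the corrected estimate, not the prediction or naïve
score, is the quantity the pipeline proposes — the choice is configurable
for sensitivity checks) versus the mean of the two clinic totals. Reported:
mean and sample SD of per-subject differences; Pearson r of the per-subject
means; r CI via the variance-stabilizing transform arctanh(r) ±
z/√(n−3), mapped back with tanh — for r = .84, n = 13 this gives
(0.538, 0.951), about 0.01 from the conventionally quoted (.55, .95),
a method-choice discrepancy documented rather than tuned away. The CI is
reported absent for n < 4.

## Problem sizes and numerical choices

- Uniformity of item sampling: 90,000 single-item draws (3-sigma binomial
  band) and 10⁵ sessions (chi-square GOF at α = 0.01).
- Exact recovery: 1,000 randomized subject-days, tolerance 1e-12.
- Rolling-statistic oracle agreement: 200 randomized histories against
  explicit-loop recomputation, tolerance 1e-12.
- Reporting-bias recovery: 50 synthetic cohorts; the mean recovered
  difference is compared with 3.02 within 3 Monte-Carlo standard errors.
- Estimator-vs-naïve MSE: 10 cohorts, compared per cohort on days with 1–8
  distinct observed items against the latent truth.
- ANOVA type-I: 1,000 null cohorts, acceptance band 5% ± 2%.
- CI calibration: with φ = 0 (no day-to-day autocorrelation) the 95% band
  around the prediction covers the latent truth on ≥ 80% of non-burn-in
  days (measured ≈ 95%); nominal coverage is not claimed, since the band
  describes the prediction's variability, not the estimate's error.
- Ties/degenerate inputs: identical ANOVA cells return F = 0, p = 1;
  zero-variance windows collapse the CI onto the prediction; an empty
  response table yields pure-fallback predictions (9 × 1.5 = 13.5).

## Known limitations

The estimator assumes responses are missing at random given the design —
true here by construction (planned missingness), but adherence in real data
may correlate with symptom state. The CI treats per-item daily means as
independent across items and days; latent autocorrelation makes it
conservative as a prediction interval for the estimate. Clinic totals rest
on two administrations, so the per-subject clinic mean is noisy, and the
per-cohort correlation of app and clinic means varies widely at n = 13.
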