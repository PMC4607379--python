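# ema-phq9

Estimating daily depression severity from a smartphone
ecological-momentary-assessment (EMA) design that never asks the whole
questionnaire at once.

## The problem

The PHQ-9 is a nine-item depression scale (items scored 0–3, total 0–27)
normally administered in full at clinic visits. A smartphone EMA design
instead delivers three short sessions per day (morning 10:00–12:00,
afternoon 13:00–15:00, evening 17:00–19:00), each showing **3 of the 9
items** sampled uniformly without replacement within the session and
independently across sessions, with occasional reverse-worded prompts.
This planned missingness keeps sessions short and fights survey fatigue, but
on most days some items are asked repeatedly and others not at all, so the
day's PHQ-9 total cannot be read off directly.

This package implements the full analysis for such a study: the design and
its validation rules, a rolling within-subject daily score estimator with
confidence intervals and deviation/suicidality flags, adherence accounting
with a time-of-day ANOVA, the app-vs-clinic score comparison, and a
synthetic cohort generator that stands in for patient data (none were ever
deposited for the original study).

## The estimator

For subject *s*, item *i* and day *d*, let *ȳ*<sub>i,d'</sub> be the mean
canonical response to item *i* on day *d'* (within-day repeats collapsed).
Writing *W(d)* = {max(1, d−14), …, d−1} for the trailing two-week window:

- **prediction** per item: *ŷ*<sub>i,d</sub> = mean of *ȳ*<sub>i,d'</sub>
  over observed days *d'* ∈ *W(d)* — never using day *d* itself; the
  predicted total is *P*<sub>d</sub> = Σ<sub>i</sub> *ŷ*<sub>i,d</sub>;
- **estimate**: *E*<sub>d</sub> = *P*<sub>d</sub> +
  Σ<sub>i ∈ observed(d)</sub> (*ȳ*<sub>i,d</sub> − *ŷ*<sub>i,d</sub>),
  i.e. observed items replace their predictions. When all nine items are
  answered once, *E*<sub>d</sub> is exactly the plain PHQ-9 sum;
- **variance**: Var(*P*<sub>d</sub>) = Σ<sub>i</sub> s²<sub>i,W(d)</sub>,
  the sum of sample variances of the per-item daily means over the window;
  the 95% CI is *P*<sub>d</sub> ± 1.96 √Var, truncated to [0, 27];
- **flags**: a day deviates high/low when *E*<sub>d</sub> leaves the CI;
  a suicidality flag is raised when any canonical response to item 9 that
  day is ≥ 2.

The naïve baseline is the missingness-weighted sum (9/m) Σ *ȳ*<sub>i,d</sub>
over the *m* distinct observed items.

## Worked example

```
ema-phq9 run --seed 2015 --out-dir out/
```

or, step by step via the numbered drivers:

```
cd analysis
python 01_simulate_cohort.py
python 02_estimate_daily_scores.py
python 03_adherence.py
python 04_app_vs_clinic.py
```

which prints, for the seed-2015 cohort:

```
overall adherence: 894/1161 = 77.00%
  morning: 287/387 = 74.2%
  afternoon: 320/387 = 82.7%
  evening: 287/387 = 74.2%
...
days with 1-8 distinct items observed: 381
  MSE vs latent truth, corrected estimate: 2.875
  MSE vs latent truth, naive weighted sum: 4.680
...
app - clinic difference: 2.82 (SD 1.97) points [generator bias: 3.02]
Pearson r of per-subject means: 0.63 (95% CI 0.13 to 0.88)
```

Reading this: of the 1161 scheduled sessions, 77% were completed, with
afternoons the most adherent slot. On days where only part of the
questionnaire was observed, the corrected estimate tracks the latent
severity substantially better than the naïve weighted sum (MSE 2.9 vs 4.7
points²). Per-subject mean app scores sit about 3 points above the clinic
scores — the reporting bias built into the generator — and correlate with
them at r = 0.63 for this single simulated cohort.

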