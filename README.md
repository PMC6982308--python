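# sleepsri

Sleep Regularity Index (SRI) analysis for minute-epoch wrist actigraphy,
built for repeated-measures cohort studies — the motivating setting is a
multi-week inpatient stay (e.g. alcohol-treatment programs) where each
participant wears an Actiwatch-style device continuously and the question
is whether, and in whom, the sleep/wake pattern becomes more regular over
time.

## The index

With epoch states `s_t ∈ {WAKE, SLEEP}` on a grid of `P` epochs per day
(`P = 1440` at 1-min epochs) and `A` the fraction of valid 24-h-lagged
pairs that agree,

    SRI = 200·A − 100

so a perfectly periodic sleeper scores 100 and independent days score
near 0. Unlike measures built on a single main rest interval (mid-sleep
variability, interdaily stability), the SRI counts every epoch, so naps
and fragmented nights move it too. Epochs with no valid data (off-wrist,
device gaps) are EXCLUDED and skipped pairwise; day-pair agreements are
averaged per window (total stay, weeks 1–3), and week-over-week deltas
feed the cohort statistics: quartile trajectory ANOVAs, a mood-disorder
group contrast, and Pearson correlations of change scores.

The pipeline:

    epoch CSV → sleep/wake scoring → eligibility filter (≥7 days;
    <4 h excluded per day in the first 21) → SRI (total/weekly/deltas)
    → nap minutes per week → cohort statistics

Because raw cohort actigraphy of this kind is rarely shareable, the
package ships a synthetic cohort generator (`sleepsri.simulate`) with
known ground truth — bedtime jitter, night-sleep fragmentation, habitual
naps, off-wrist blocks, mood/exhaustion covariates with configurable
couplings — used throughout the test suite for calibration and
effect-recovery checks.

## Worked example

```python
from sleepsri import SleepRegularityModel, generate_cohort, get_scenario

scenario = get_scenario("mood_gap", n_participants=60, seed=7)
series, covariates, truth = generate_cohort(scenario)

model = SleepRegularityModel(series, covariates=covariates)
results = model.fit()
print(results.summary())
```

prints (abridged):

```
Sleep Regularity Index cohort analysis
==========================================
Participants: 60 recorded, 60 eligible, 0 dropped
...
Total SRI: mean 71.27 (SD 6.75), range 61.53-87.37, n=60
Weekly SRI, mean (SD):
  week 1: 71.11 (7.06), n=60
  week 2: 71.50 (7.20), n=60
  week 3: 71.25 (7.09), n=60
...
Mood-disorder contrast on total SRI (one-way ANOVA): F(1, 58) = 16.00, p = 0.0001815, n = 60
  mood mean 68.64 (SD 4.65, n=35) vs no-mood 74.96 (SD 7.56, n=25)

Delta correlations (delta SRI w3-w1 vs):
  dsri_w3_w1_vs_d_nap_minutes: r = -0.103, p = 0.4343, n = 60
  ...
```

Reading it: every participant passed the eligibility filter; the cohort's
total SRI sits in the mid-70s with ~7 points of between-participant
spread (typical for clinical actigraphy cohorts); the simulated
mood-disorder subgroup shows the designed ~5-point regularity deficit,
picked up by the two-group contrast; and with no nap–regularity coupling
in this scenario the change-score correlations are near zero. The fitted
results object also exposes `participant_table`, `sri_table()`,
`weekly_table()`, `quartiles()`, `quartile_trajectories()`,
`delta_correlation_table()` and matplotlib helpers
(`plot_weekly_trajectories`, `plot_delta_scatter`).

## Command line

```
sleepsri simulate --scenario filtering_demo --seed 7 --out cohort/
sleepsri analyze  --input-dir cohort/ --out analysis/
sleepsri replicate --scenario quartile_improvement --seed 1 --out run/
```

`simulate` writes per-participant epoch CSVs plus covariate/truth tables
and a manifest; `analyze` runs the full pipeline (every dropped
participant is logged with its reason) and emits tidy CSVs
(`sri.csv`, `participants.csv`, `statistics.csv`, `missingness.csv`) and
a markdown report; `replicate` chains both. Filter and scorer knobs are
flags (`--min-days`, `--max-excluded-hours`, `--horizon-days`,
`--wake-threshold`, `--sri-mode`).

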