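# Methods

## The Sleep Regularity Index

The Sleep Regularity Index (SRI) measures the day-to-day repeatability of a
sleeper's sleep/wake pattern from epoch-scored actigraphy. Let `s_t ∈
{WAKE, SLEEP}` be the scored state of epoch `t` on a regular grid of `P`
epochs per day (`P = 1440` at one-minute epochs), and call the pair
`(t, t+P)` *valid* when both states are known (neither epoch excluded).
With `A` the probability that a valid pair agrees (`s_t = s_{t+P}`),

    SRI = 200·A − 100.

A perfectly periodic sleeper scores 100; a pattern whose days are
independent scores near 0. The formula admits −100 for a pattern that
anti-repeats day over day (sleeping exactly when awake the day before);
the index is deliberately *not* clamped to [0, 100] even though negative
values do not occur in practice — the transform is reported as computed.

Two averaging conventions are implemented because the phrase "averaging all
SRIs in the time interval" is ambiguous when data are missing:

* **daily** (default): agreement is computed per day pair (day `d` against
  day `d+1`) and the per-pair agreements are averaged with equal weight,
  regardless of how many valid epoch pairs each contributes;
* **pooled**: all valid epoch pairs in the window are pooled with equal
  weight.

The two are provably identical whenever no epoch is excluded (every day
pair then contributes exactly `P` pairs), which the test suite verifies; on
incomplete data they differ slightly and the choice is surfaced as
`sri_mode`.

Windows: TOTAL covers every recording day; week `k` covers day pairs whose
*first* day lies in days `7(k−1)+1 … 7k`. Days are recording days anchored
at the first observed epoch — inpatient recordings begin mid-day at
enrollment, and nothing in the index anchors to midnight. Weekly change
scores (deltas) are week3−week1, week2−week1, week3−week2, each defined
only when both weekly SRIs exist; missing values propagate as nulls and
every downstream analysis deletes listwise, carrying its own n.

## Scoring stand-in

The vendor algorithm that scored the original recordings is proprietary.
The package implements the published weighted-window rule: the score of
epoch `t` is `Σ w_k·a_{t+k}` over the epoch and two neighbours each side
with weights (1/25, 1/5, 1, 1/5, 1/25); the epoch is WAKE when the score
reaches the threshold (default 40, the "medium" sensitivity). Excluded
epochs are never scored; when the window overlaps excluded epochs or the
recording boundary, the available weights are rescaled to the full kernel
mass so the threshold keeps its scale. Scoring is monotone in every
activity count (raising a count can only move epochs toward WAKE), a
property under test.

Naps are operationalised as scored sleep bouts that *start* inside a
daytime clock window (08:00–20:00) and last ≥ 10 minutes; both knobs are
policy fields because the source analyses derived naps from actigraphy
without stating a rule. Excluded epochs break bouts — an unknown state is
never asserted asleep. Shorter daytime bouts remain in the bout list with
`is_nap=False`, so bout minutes always partition the SLEEP epochs exactly.

## Eligibility and missingness

Mirroring the inpatient study design the defaults come from: a participant
needs at least 7 recorded days (a day counts when it has ≥ 1 valid epoch),
and is excluded when any day within the first 21 has ≥ 4 h of excluded
data. The checks run in that order, so a participant failing both is
reported under the minimum-days rule. The missingness report counts, for
thresholds 2/4/6 h, participants with at least that many excluded hours on
some day within the horizon; counts are monotone non-increasing in the
threshold by construction.

## Statistical battery

* Weekly trajectories: one-within-factor repeated-measures ANOVA computed
  from the sums-of-squares partition (subject, week, residual), df =
  (k−1, (n−1)(k−1)), no sphericity correction by default
  (Greenhouse–Geisser optional). Weekly SRIs for a participant come from
  disjoint day-pair sets, so compound symmetry is a reasonable default; the
  implementation is cross-checked against statsmodels' AnovaRM in tests.
* Quartile stratification: among complete cases (non-null SRI at weeks
  1–3), sort by week-1 SRI (ties by participant id), bottom/top
  `floor(n/4)` — 99 complete cases yield groups of 24.
* Group contrast: two-group one-way ANOVA on total SRI by mood-disorder
  status, with the equivalent pooled two-sample t (F = t² is asserted to
  1e−9).
* Delta correlations: Pearson r with two-sided p from the t transform
  (n−2 df), listwise per pair; no multiplicity correction by default
  (exploratory framing), with an optional Benjamini–Hochberg column.

Change scores are coded naturally as week3 − week1 throughout. Improved
regularity therefore appears as a *negative* correlation with exhaustion
change (less exhaustion late in the stay), and with nap-duration change.

## Synthetic cohorts

No raw actigraphy at the target scale is publicly deposited, so the
pipeline is validated against generated cohorts with known latent
structure. Each participant gets a nightly main sleep period (onset =
habitual bedtime + N(0, jitter SD); duration normal, truncated to
[240, 720] min), naps, brief within-night awakenings, optional off-wrist
blocks, and activity counts drawn sleep-low/wake-high so the default
scorer recovers truth states with ≥ 95% epoch accuracy (the generator is
calibrated to the scorer, not vice versa).

A design point worth recording: weekly SRI estimated from only 7 day pairs
is intrinsically noisy, and selecting quartiles on week-1 SRI then
regresses strongly to the mean — enough, in a jitter-dominated generator,
to make the *top* quartile's trajectory spuriously significant almost
always. Real cohorts do not behave that way, which indicates that most of
a person's SRI deficit is stable within-person week to week. The generator
therefore draws most of the deficit from low-week-to-week-variance
mechanisms:

* **night-sleep fragmentation** (the WASO analogue): each night-sleep epoch
  flips to brief wake with probability ~0.125 (≈ 55 min WASO per night,
  matching the study population's scale). Across ~350 overlapping sleep
  minutes per day pair this produces a near-deterministic agreement
  deficit — it moves the SRI *level* with very little weekly noise — and
  its between-participant spread (SD 0.12) is the main regularity axis;
* **habitual-time naps**: one nap most days (Bernoulli per day at rates
  ≤ 1, Poisson above), centred on a personal nap time (default 14:00,
  SD 12 min), duration ~35 min — ≈ 205 nap minutes per week. Setting the
  nap-time SD large (e.g. 240 min) recovers effectively uniform daytime
  placement, used where naps must decouple from the daily routine;
* **bedtime jitter** (SD ~16 min, between-participant SD 18) contributes
  the remainder and the week-to-week sampling noise.

Defaults yield a cohort with mean total SRI ≈ 75, between-participant SD
≈ 7, weekly noise ≈ 2 SRI points — the scale of the population the
pipeline targets. No claim of distributional fidelity to any real
recording is made beyond these summary magnitudes.

Packaged scenarios (all reproducible from a single seed; participant `i`'s
stream is keyed by (seed, i)):

* `regular_baseline` — cohort-scale defaults (n=124, 24 days, mild
  off-wrist missingness).
* `filtering_demo` — 10 participants: 2 short recordings (5 days), 3 with
  a ≥ 4 h off-wrist block every day, 5 clean; the eligibility filter keeps
  exactly 5.
* `quartile_improvement` — participants whose jitter and fragmentation
  exceed the cohort mean decay toward it at 35%/week, concentrating
  improvement in the least-regular quartile while the top quartile stays
  flat.
* `mood_gap` — a 70/50 mixture where the mood-disorder profile carries
  higher fragmentation and jitter (true gap ≈ 4.5 SRI points at pooled SD
  ≈ 7), detectable by the two-group test in well over 80% of cohorts.
* `nap_coupling` — uniform-time naps whose weekly load varies
  (target 215 ± realized-Poisson + 60 min/week); realized naps mechanically
  lower that week's SRI (≈ −0.028 SRI per weekly nap minute), and bedtime
  jitter of 50 min supplies decorrelating noise, producing a designed
  ΔSRI–Δnap correlation of ≈ −0.6.
* `exhaustion_coupling` — weekly exhaustion change generated as
  ρ·z(ΔSRI) + √(1−ρ²)·ε with ρ = −0.24 against the cohort-standardised
  truth ΔSRI.
* `null_everything` — no trends, no couplings, random mood labels; used
  for type-I calibration.

Covariate generation (mood/anxiety flags, weekly 0–10 exhaustion scores)
uses a separate per-participant stream so covariates never perturb the
actigraphy draw.

## Numerical and design choices

* Gaps in input CSVs are filled with EXCLUDED epochs so the 24-h lag is
  index arithmetic; timestamps off the inferred grid are a structural
  error, not silently snapped.
* Timestamps are timezone-naive local time; DST transitions are out of
  scope (synthetic recordings never cross one).
* A null SRI (no valid pairs) propagates as null — never 0 — through
  deltas and into listwise-deleted statistics.
* Degenerate repeated-measures inputs: zero residual *and* zero week SS
  (identical weekly values) reports F = 0, p = 1; zero residual with a
  week effect reports F = ∞, p = 0.
* Quartile ties are broken by participant id for determinism; cohorts
  below 8 complete cases refuse to stratify.
* Truncated-normal draws use rejection with a 100-draw cap, then clip —
  deterministic given the stream, and exact for the SD = 0 edge case.

## Validation strategy and problem sizes

The test suite validates against independent oracles (pure-Python loop
implementations of the SRI, textbook sums of squares, direct correlation
formulas, statsmodels AnovaRM), against analytic fixed points (perfect
sleeper → SRI exactly 100; complement and whole-day-translation
invariance), and against the generator's truth tables. Statistical
calibration and effect-recovery suites run on truth states with 24-day
cohorts (type-I: 10,000 cohorts of n=8; effect recovery: 200 cohorts each
at the study-shaped sizes n=99, 46 and 120); scorer fidelity is assessed
separately on activity counts (50 clean 21-day participants). Passing
these suites shows the pipeline computes the intended quantities and
recovers designed effects at realistic magnitudes; it cannot certify
distributional fidelity to any particular device or population.

## Known limitations

* The scorer is a documented stand-in, not the vendor algorithm; absolute
  sleep-parameter values (efficiency, WASO) from it should not be compared
  against vendor outputs.
* The nap rule (daytime window + minimum duration) is one defensible
  operationalisation; diary-assisted nap marking is out of scope.
* The generator has no circadian mechanics (no light input, no two-process
  dynamics) and no autocorrelated bedtime drift; it emulates the
  statistical shape the analysis consumes, nothing more.
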