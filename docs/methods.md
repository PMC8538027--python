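# Methods

This note documents the analysis conventions, the synthetic-data model, the
numerical choices, and the limitations of `actistep`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Time and data model

All timestamps are naive local clinic time; days are calendar days on that
clock and no DST arithmetic is applied, because the daily activity window
is defined on wall-clock hours. The epoch grid is one minute; sub-minute
device exports must be pre-binned upstream. Missing numeric cells are
*absent* (`None`/`NaN`), never zero, and nothing is imputed at the I/O
layer — the only imputation-like behavior in the package is the wear
normalization, which lives in `wear_aggregation` where it is auditable.

## Wear detection and daily normalization

A minute counts as worn iff an epoch exists for it **and** carries a
heart-rate sample. Optical heart-rate sensing requires skin contact,
whereas a step counter can register motion off the wrist, so HR presence is
the most conservative observable wear proxy. The activity window is
6 AM–midnight (18 h = 1080 min); epochs outside it are ignored entirely,
not re-attributed.

Daily raw totals (distance, steps, stand-ups) are sums over worn window
minutes; normalized totals scale them to the full window with one global
linear factor, `norm = raw / wear_fraction`. No within-day circadian
reweighting is attempted. A day with wear fraction < `min_wear_fraction`
(default 0.10) is missing and carries no normalized values. Heart rate is
an intensity, not a count: it is averaged over worn minutes and never
scaled. Normalization is applied uniformly to all three counts, including
standing-up events.

Under uniform random minute masking the estimator is unbiased; the
acceptance suite verifies the 2%-level agreement on 1,000 synthetic days.
Block-wise (non-uniform) wear can bias the estimator when activity has a
circadian profile; see "Generator" below for how the simulation keeps its
own wear schedule coverage-uniform.

## Baseline, end of observation, and change scores

Baseline = median of non-missing daily values over the 14 calendar days
strictly before the date of first inhalation (the treatment-start day
itself belongs to the observation period). End = median over the last 14
calendar days of observation. Medians use the midpoint convention for even
n; cohort dispersion is reported as IQR with type-7 (linear interpolation)
quartiles, the common statistical-software default, documented here
because the convention is otherwise arbitrary.

Per-patient change = end − baseline, defined only when both period values
exist. The cohort-level change is the **median of per-patient changes**,
which is not in general the difference of the two cohort medians; a
dedicated test pins this distinction.

The full-analysis-set filter admits a patient iff they are in the safety
set (≥ 1 dose, consent not withdrawn), are not a screening failure, have
≥ 3 non-missing activity days in the baseline window and ≥ 3 in the last
two weeks of observation, and have at least one clinical outcome (6MWD,
WHO FC, BNP or NT-proBNP — the same marker at both visits) available at
both visits. "Last two weeks" is identified with the same last-14-day
window as the end summary; using a single window definition avoids two
subtly different end periods.

## Event-aligned post-inhalation curves

For each inhalation session, 12 consecutive 15-minute bins begin at the
session end, rounded up to the next whole minute to match the epoch grid.
Bin values are raw sums over worn minutes. The exclusion rule: a session is
dropped iff any minute of bins 2–12 is unworn; the first bin may be
partially worn, is counted as such, and its raw (unscaled) sum is used.
This reconciles an all-or-nothing "worn over the entire 3 hours" rule with
the reality that coverage of the first interval right after handling the
nebulizer is often incomplete. A strict mode
(`AnalysisConfig(strict_alignment=True)`) excludes on any unworn minute
anywhere. Overlapping 3-hour windows of nearby sessions contribute
independently; complete and incomplete inhalations both enter; sessions
are attributed to the calendar date of their end time.

Averaging is three-level: bin-wise over each patient-day's included
sessions, then bin-wise across all patient-day vectors. The implementation
is checked bit-for-bit against a brute-force minute-enumeration oracle.

No adjustment is made for the unequal distribution of inhalation times
across the day, and no deconvolution of overlapping pharmacologic effects
is attempted.

## Walk-test endpoints

The digital 6MWD is an explicit stride model, `distance = steps × stride`.
The default stride (0.78 m) represents a healthy-adult calibration and
deliberately over-estimates distance in patients with a shortened gait —
which is why a per-patient stride can be supplied. Resting HR is the mean
over worn zero-step minutes: over the whole activity window for the daily
value (requiring ≥ 5 qualifying minutes), over the 5 minutes before test
start for the pre-test value (≥ 1 qualifying minute). The chronotropic
response is `max(in-test HR) − resting HR`. In-test changes are
`HR(minute k) − HR(minute −1)` for k = 1..6. The recovery curve is
`HR(end + t) − HR(end)` at t = 0.5, 1, …, 3 min on the minute grid with
linear interpolation at half-minutes; negative values mean recovery. The
sub-minute HR cadence of real devices is collapsed to the minute grid —
an explicit simplification.

## Cohort statistics

Correlations are sample Pearson r on complete pairwise observations, with
the per-pair n recorded and pairs with n < 10 flagged as too small to
interpret. No imputation, no multiplicity adjustment, and no confidence
intervals by default (the analyses are exploratory and descriptive); a
seeded percentile bootstrap is available behind a flag, as is a
complete-case sensitivity mode. BNP and NT-proBNP stay separate columns
because sites measure one or the other. Change-on-change regressions are
OLS on complete cases via statsmodels, emitted both per predictor and
jointly over daily distance, stand-ups and digital 6MWD, since either
reading of "digital measures as independent variables" is defensible.

## Generator

The synthetic cohort emulates the study conditions: 18 patients, a 4–14
day baseline followed by 91 observation days, ~5 Poisson-scheduled
sessions/day of lognormal ~5.5 min (90% complete, 2.5 µg), wear hours
uniform on 4.8–11.5 h/day, a latent daily distance of mean 5.2 km
(between-patient SD 2 km, day-to-day CV 0.15), a two-peak circadian
profile, resting HR ~N(76, 8) with HR = rest + 0.25 × steps/min + noise,
a +20% post-inhalation boost decaying with a 60-minute constant, and a
+0.4 km gradual treatment effect ramping linearly to the end of
observation. Wherever the emulated study publishes a cohort median, that
median is the configured default; remaining scales (noise SDs, HR slope,
circadian shape) were fixed once at values a wearables analyst would call
realistic and are not tuned.

Mechanics worth knowing:

- **Wear blocks are rotation-uniform.** Daily wear is 2–4 contiguous
  blocks placed by a random composition and then circularly rotated within
  the window, making each minute's coverage probability flat so that
  normalized totals stay unbiased despite the circadian profile.
- **The boost refreshes rather than stacks.** The multiplicative factor is
  `1 + A·exp(−Δ/τ)` with Δ the minutes since the **most recent** session
  end — a saturating, dose-refreshed effect. With session gaps above the
  3-hour analysis horizon this makes the injected profile available in
  closed form (`expected_alignment_curve`), which the boost-recovery test
  exploits by scheduling 4 fixed sessions/day on a flat background.
  The default Poisson schedule produces overlapping windows, as real
  dosing does.
- **Ground truth carries the noiseless expectation.** Each patient's
  expected daily distance per calendar day (full-wear basis, including
  ramp and boost) is stored, so recovery tests compare the pipeline
  against exact truth instead of re-deriving it. Note the observed change
  from baseline exceeds the bare ramp parameter, because the boost only
  exists once sessions begin — a modeled mechanism, not an artifact.
- **Determinism.** One root seed spawns one `SeedSequence` per patient;
  regeneration under identical parameters is byte-identical, which the
  suite checks by hashing the written cohort directory.
- Visit records tie the traditional 6MWD to the latent stride and a
  walk-test step count that shifts with the realized per-patient effect,
  so traditional-vs-digital change correlations emerge mechanistically
  rather than being dialed in; heart-rate recovery is generated slower at
  the final visit.

What the generator does **not** model — and hence what passing tests do
not establish about real data: device-specific step-detection error,
off-wrist motion artifacts, non-wear that correlates with symptoms or
activity (informative missingness), dropout and consent withdrawal,
weekday/weekend structure, pharmacokinetics beyond the single-exponential
boost, and adverse events.

## Problem sizes and numerical choices

The test suite runs the heavier oracles at deliberately chosen sizes: the
normalization oracle on 1,000 days, the boost recovery on 50 patients × 90
days with 4 sessions/day, the statistics oracles on 100 random tables of
3–10 rows. These sizes give Monte-Carlo error comfortably inside the
asserted tolerances (2%, 10%, 1e-8 respectively) while keeping the whole
suite in the minutes range on a single CPU.

Tie-breaks and degenerate inputs: zero eligible days yield absent medians
(never zero); zero included sessions raise `EmptyCurveError`; zero-variance
columns yield absent r with a recorded reason; rank-deficient regression
designs raise an error naming the collinear predictors; a session ending
mid-minute aligns to the next whole minute; a date outside stream coverage
has zero worn minutes rather than being an error.

## Known limitations

Wear detection by HR presence cannot distinguish a charging watch worn on
a table edge case from true non-wear. The constant-stride 6MWD is linear
in steps by construction and will not capture gait-speed-dependent stride.
The 18-hour window convention discards genuine nocturnal activity. The
full-analysis-set filter treats the safety flags as supplied inputs; no
per-protocol set is implemented. Correlation outputs are descriptive —
with cohorts of ~18 patients the sampling error of r is large, which is
exactly why per-pair n and the low-n flag are always reported.
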