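# Methods

## Metrics and missing-data semantics

IV and IS are ratios of sums of squares over hourly mean activity (see the
README for the formulas). The package computes them from 30-s epoch records in
two steps: hourly binning, then the metric sums.

**Hourly binning.** Each clock hour's value is the arithmetic mean of its
available (non-absent) epochs. Genuine zeros — including zeros injected by the
non-wear masking phenotype — are ordinary data and enter the mean; only absent
(NaN) epochs are excluded. An hour whose 120 epochs are all absent is itself
absent. This is exactly the distinction the two masking phenotypes probe: a
device off the wrist keeps recording (zeros change the data), a device that
stops recording leaves holes (absent hours change the term counts).

**Absent hours in IV/IS.** The classical formulas assume complete data, and no
standard convention exists for gaps. We use available-case deletion with count
adjustment:

- the grand mean and the shared denominator run over the valid hours
  (n_used replaces n);
- IV's numerator runs over consecutive pairs whose members are both valid
  (m pairs replace n−1);
- IS's hour-of-day bins average over the days valid at that bin; bins with no
  valid day are dropped (p_used replaces 24).

Under this convention NaN masking leaves IV nearly unbiased and biases IS
mildly upward, which is the behaviour the heatmap analysis quantifies.
Degenerate denominators (e.g. a constant hourly series after extreme masking)
yield an UNDEFINED (NaN) metric, which downstream Bland–Altman summaries drop
pairwise while recording the surviving pair count — never an exception and
never a silent fill.

The often-quoted statement that IV ranges from 0 to 2 is descriptive of real
data, not a mathematical bound (a strictly alternating series reaches 4); the
package asserts only IV ≥ 0 and 0 ≤ IS ≤ 1 for complete whole-day data.

**Term-count sensitivity.** The analytic fraction of metric terms touched by a
contiguous gap uses the printed per-gap-hour convention for IV
(gap_hours/(n−1); one hour in a week → 1/167 ≈ 0.6%), even though an interior
hour strictly enters two consecutive-difference terms; the strict count is
exposed as `iv_affected_pair_count`. For IS the fraction is gap-touched
hour-of-day bins out of 24 (one hour → 1/24 ≈ 4.2%).

## Masking grids

Masks operate at epoch (30-s) resolution, before hourly binning, because the
imputation and binning order matters: mask → impute → bin → metrics.

- **Single gaps:** durations 1, 3, …, 23 h crossed with start hours
  0, 2, …, 22, per start day 1–7 and per phenotype (144 cells per day ×
  phenotype on interior days). The duration list reads "1 to 23 h in 2-h
  increments" as {1, 3, …, 23}; the generator takes the list explicitly so any
  other reading is runnable.
- **Double gaps:** bouts of 115 and 140 min (the representative first- and
  second-bout durations; the harmonic means underlying them are 113 and
  136 min) with separations 3, 5, …, 47 h crossed with the same start hours.
  Separation is measured from the end of bout 1 to the start of bout 2 — the
  data-present interval between the gaps — since "duration between bouts" does
  not pin the endpoints; results are labelled so they can be re-indexed under
  the other convention.

Grid cells whose bouts would cross the end of the 7-day record are omitted at
generation time and surface as empty (NaN) heatmap cells.

## Imputation

All three imputers fill only the epochs inside the declared bouts; the bout
list, not the stored value, defines the gap, so zero- and NaN-masked inputs
impute identically (the evaluation pipeline exploits this and computes imputed
conditions once per mask geometry).

- **Linear:** the line through the last valid epoch before and the first valid
  epoch after the gap. A gap touching the record boundary has no flank on one
  side; the available flank is held constant across the gap and a warning is
  logged (the interpolation line is undefined there; the default grids never
  hit this case).
- **Mean ToD / median ToD:** each gap epoch is replaced by the mean (median)
  of the same clock-time epoch on donor days. Donors are all days whose epoch
  at that clock time is neither inside any masked bout nor absent — masked
  zeros are known-spurious and are never donors. The printed mean-ToD formula
  normalizes a sum over N instances by 1/(N−1); we implement the mean over the
  N−1 non-missing days, which is what the accompanying prose describes. With
  an even donor count (the common case: 6 donors in a 7-day record) the median
  is the mean of the two central order statistics.

A gap spanning every instance of some clock time (≥ 7 days) has no donors and
raises an error naming the first affected epoch.

## Bland–Altman evaluation

For each grid cell, per-participant metric values from the adulterated record
(masked, or masked-then-imputed) are compared with the unadulterated record's:
difference = test − true, average = (test + true)/2. The summary holds the
mean difference (bias), the n−1 sample SD and the 1.96 × SD half-width of the
limits of agreement, and the OLS slope and intercept of difference on average
(the conventional proportional-bias regression; the source analysis names a
"linear fitted slope" without specifying the regression). When every average
is identical the OLS slope is undefined; we define it as 0 when the
differences are also constant (so self-agreement is exactly (0, 0, 0)) and
UNDEFINED otherwise. Pairs with an UNDEFINED member are dropped and `n_pairs`
records the survivors, keeping the choice auditable.

Heatmaps hold one statistic per cell for each metric × condition × start day;
the canonical serialization is a long-format CSV, with an optional basic
matplotlib rendering (`evaluation.render_heatmap`).

## Synthetic cohort generator

The generator emulates the processed output of a wrist accelerometer pipeline:
7-day, midnight-aligned, 30-s epoch vector-magnitude records in milli-g. The
24-h template is a night baseline (4 mg) raised to a daytime plateau (35 mg)
through raised-cosine morning (06:30, 1.5 h) and evening (21:30, 2 h)
transitions, plus a raised-cosine midday bump (+22 mg at 13:00, ±4.5 h) — the
simplest shape with the midday activity peak that the timing findings depend
on. Per-day randomness: a lognormal amplitude factor (sd 0.18 in log units)
and a Gaussian phase shift (sd 40 min). Within days: a per-clock-hour
lognormal modulation (sd 0.55) for hour-scale behavioural variability, a
per-epoch lognormal noise factor (sd 0.55), and ~10 brief activity bursts per
day (exponential amplitude, mean 60 mg, ~2 min long).

Defaults were calibrated once so that a clean 20-record cohort's median IV and
IS fall inside wide bands around values observed in large community samples
(median IV in [0.6, 1.3], median IS in [0.35, 0.75]; at the defaults the
cohort medians are ≈ 1.1 and ≈ 0.49) and then frozen. The cohort is a test
substrate, not a population clone: it has no demographic structure, non-wear
behaviour, weekday/weekend asymmetry, or seasonal variation, so passing tests
demonstrate the pipeline's behaviour under a plausible diurnal signal, not
population-level generalization.

One top-level seed derives an independent per-participant stream via numpy
SeedSequence spawning with the PCG64 generator (pinned in the cohort
manifest), so any single record can be regenerated in isolation and cohorts
are bit-reproducible across runs.

A note on which knob drives which metric: per-epoch noise averages out over
the 120 epochs in an hourly bin and barely moves IV; the hour-scale modulation
is what raises IV, and the day-level amplitude/phase jitter is what lowers IS.
The property tests assert these monotonicities (three levels, 20 records,
fixed seeds).

## Problem sizes and numerical choices

The simulation studies in the test suite and acceptance script use
20-participant cohorts and a single start day for the full single-gap grid
(144 cells × 2 phenotypes × 4 conditions) — large enough for stable
cohort-mean Bland–Altman cells (the per-cell max |IS bias| after median-ToD
imputation varies by < 0.01 across seeds), while a full run over all 7 start
days and both grids remains available through the CLI. Input validation is
strict (uniform 30-s spacing, midnight alignment, whole days, non-negative
values); records that start mid-day must be truncated to whole days upstream,
a requirement imposed here so that hour-of-day labels are unambiguous.
Floating-point comparisons in tests use 1e-12 relative tolerance against naive
double-loop oracle implementations of IV/IS.

## Known limitations

- The absent-hour deletion convention is declared, not inferred from any
  reference implementation; other conventions (dropping whole records, or
  whole days) would change the NaN-phenotype results.
- Linear imputation at record boundaries falls back to a constant flank.
- The double-gap separation convention (end-to-start) shifts the separation
  axis by ~2 h relative to a start-to-start reading.
- The synthetic cohort omits many features of free-living data (non-wear
  streaks, weekday structure, device artefacts); conclusions about imputation
  accuracy on real data should be re-checked against a real cohort.
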