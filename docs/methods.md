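# Methods

## Data contract and validation

A CGM dataset is a long table of (subject id, timestamp, glucose in
mg/dL). On read, rows with unparseable timestamps or non-positive /
non-finite glucose are dropped and counted (sensor artifacts are common
enough that a hard error would make real exports unreadable; the
validation report preserves auditability). Exact duplicate
(subject, timestamp) pairs are collapsed keeping the first occurrence —
a deterministic, order-stable rule. After validation, timestamps are
strictly increasing within each subject, so every downstream metric is
invariant under input row permutation.

Timestamps are naive local wall-clock times; day boundaries are local
midnight. mg/dL is the canonical unit everywhere inside the package;
mmol/L conversion (factor 18.0, consistent with the g/18 inside the
GRADE transform) exists only at the I/O edge.

## The day-by-day grid

Metrics that compare readings across days or at fixed lags need
measurements on an equidistant grid, aligned across days and across
subjects whose sensor clocks disagree. `day_by_day` builds, per
subject, a matrix with one row per calendar day and one column per
grid slot.

- **Grid convention.** Column *j* (1-based) is the time of day
  *j·dt0* minutes after local midnight; a 5-minute grid has 288
  columns at 00:05 … 24:00. A fixed convention is required for MODD and
  the between-day SD subtypes; cross-implementations that anchor the
  first column at offset 0 instead will disagree by exactly one column.
- **dt0 inference.** The rounded median of successive time differences,
  clamped to the nearest divisor of 1440. The median is robust to
  gaps; the divisor constraint makes whole days tile exactly.
- **Gap policy.** A grid point is linearly interpolated between its two
  bracketing observations iff they are at most `inter_gap` minutes
  apart (default 45; a gap of exactly 45 minutes is still
  interpolated). Larger gaps yield missing cells. No extrapolation
  before the first or after the last observation: the leading cells of
  the first day and trailing cells of the last day are missing rather
  than invented.
- **Active percent** is the fraction of expected grid slots
  (⌊span/dt0⌋ + 1 over the observed span) actually hit by a reading,
  capped at 100%. Using the observed span rather than whole days keeps
  the day count fractional, matching how wear time is reported.

## Statistical conventions

- Sample standard deviations (denominator n − 1) everywhere, matching
  the R conventions under which the reference values for these metrics
  were originally produced.
- Quantiles by linear interpolation of order statistics (numpy's
  default, equivalent to R type 7).
- MAD scaled by 1.4826 (normal consistency), R's default.
- Percent-above and percent-below use strict inequalities; in-range is
  inclusive at both ends, so above + below + exactly-equal partitions
  to 100 exactly.
- Missing cells are handled by pairwise deletion in every grid metric;
  rows, columns or blocks with fewer than two observed cells are
  skipped. A metric with no qualifying observations returns NaN, never
  0 — zero is a valid metric value and the two must stay
  distinguishable. One consequence worth knowing: on a 60-minute grid
  SdWSH is NaN by construction (each 1-hour block holds one cell).

## Metric definitions and choices that were genuinely open

- **GRADE**: per reading h(g) = 425·(log₁₀log₁₀(g/18) + 0.16)²,
  capped at 50; the score is the mean of h and the eu/hypo/hyper
  percentages attribute Σh to readings in [70, 140], below, and above.
  Values ≤ 18 mg/dL (physiologically impossible; the double log is
  undefined there) are clamped just above 18 with a warning. For a
  trace sitting exactly at the transform's zero (≈ 88.5 mg/dL) the
  attribution denominator vanishes; the percentages then fall back to
  simple count fractions.
- **LBGI/HBGI**: f(g) = 1.509·((ln g)^1.084 − 5.381), risk 10·f²
  assigned to the low or high side by the sign of f and saturated at
  100 (the intended range of the risk scale). f crosses zero near
  112.5 mg/dL.
- **ADRR** groups readings by local calendar day (the same convention
  as the grid rows) and averages, over days, the maximum low risk plus
  maximum high risk.
- **GVP** uses raw timestamped readings; segments spanning gaps longer
  than `inter_gap` are excluded, since an unbounded Δt both distorts
  the flat-line baseline L0 and contributes almost no excess length.
- **CONGA, MAG, rate of change** operate on the day-concatenated grid,
  crossing midnight. This mirrors which metrics conventionally consume
  the interpolated grid. CONGA values are known to disagree across
  implementations precisely because of interpolation and missing-data
  handling, so no external CONGA value is treated as exact here.
- **MAGE** defaults to the classical 1-SD exceedance rule: the mean of
  |g − mean| over readings deviating by more than one sample SD. This
  is the reproducible reading of the original definition and what
  contemporaneous implementations computed. A moving-average-crossing
  variant (short/long MA crossings delimit excursions; amplitudes
  exceeding one SD are averaged) is available behind
  `mage(..., variant="ma_crossing")` but is not the default.
- **SdWSH** uses consecutive non-overlapping 1-hour blocks — the
  simplest reproducible reading of the "within series per hour"
  subtype; rolling-window implementations will differ slightly.
- **Hypo index** defaults to LLTR = 80 mg/dL with exponent 2 and
  scale 30, following the published index scheme; all four constants
  are parameters.

## Tunable parameters

All thresholds in mg/dL, durations in minutes unless noted:
percent-above targets (140, 180, 250), percent-below targets (54, 70),
in-range bands ([70, 180], [63, 140]), ULTR 140 / LLTR 80 with
exponents 1.1 / 2.0 and scales 30 / 30, M-value reference 90, CONGA lag
1 h, MAG sampling 60 min, ROC lag 15 min, `inter_gap` 45 min, `dt0`
inferred, quantile probabilities (0, 25, 50, 75, 100)%, AGP cutoffs
(54, 70, 180, 250), lasagna midpoint 105 and limits (50, 500), GRADE
euglycemic window [70, 140], MAD constant 1.4826. All live in one
frozen `MetricParams` dataclass; the CLI exposes the ones users
commonly change.

## AGP report

The report uses the most recent `maxd` days (default 14, the span
generally considered sufficient for a reliable profile). Bands follow
the consensus convention at the printed cutoffs: <54, 54–69, 70–180,
181–250, >250, with boundary values 54/70/180/250 falling in the
bands 54–69, 70–180, 70–180 and 181–250 respectively; every reading is
assigned to exactly one band and the five percentages sum to 100. The
quantile ribbons (5/25/50/75/95%) are computed per grid column across
days (pairwise-complete), so days are aligned exactly as the gridder
aligns them. Output formats are PNG and a self-contained HTML file with
the figure embedded as base64 — diffable, dependency-free artifacts
rendered from a single built-in template. Rendering contains no
randomness.

Lasagna plots map glucose to color through a two-slope gradient:
limits → endpoints, midpoint (default 105 mg/dL) → center. The
blue-red scheme interpolates three anchors (blue → white → red) so
that a higher glucose value is never bluer; the red-orange scheme uses
a documented four-anchor gradient (red → green → yellow → orange) with
green near the in-range center — pixel parity with any particular
other implementation is not a goal. Data outside the limits are
clamped with a warning. Sorting modes: `timesorted` sorts within each
column, `subjectsorted` within each row, both descending with missing
values kept trailing.

## Synthetic data generator

`simulate_cgm` emulates the structure that matters to the metric
layer: per-subject baseline level; a 24-hour sinusoid (default
amplitude 25 mg/dL peaking at 17:00, where post-prandial afternoon
highs sit); gamma-shaped meal excursions (Poisson count per day,
default 3, peaking ~45 minutes after onset, waking hours only); AR(1)
sensor noise (default marginal SD 15 mg/dL, lag-1 coefficient 0.7 at
the 5-minute period — autocorrelated noise is essential, because white
noise makes rate-of-change and CONGA-type metrics degenerate to
dt-dominated values); per-reading dropout (2%) and contiguous gap
blocks (0.3/day, 90 min) to exercise the `inter_gap` logic; and a
per-subject clock offset (SD 40 s) so grids are misaligned across
subjects as they are in reality. Glucose is floored at 40 mg/dL to
keep the log-based transforms in-domain, and rounded to 0.1 mg/dL like
sensor exports.

The fixed phenotype panel (5 subjects, 14 days at 5 minutes) encodes
one chronically hyperglycemic, low-variability subject (baseline
220 mg/dL, noise SD 6), one labile subject (baseline 140, noise SD 35,
meal amplitude 90), and three intermediates (baselines 118/135/175).
The intermediate means are spaced widely enough that the ordering of
percent-above-180 follows the ordering of the means by construction —
with closely spaced means the labile subject's heavy upper tail would
break that correspondence.

What the generator does **not** emulate: insulin–glucose dynamics,
meal timing habits, sensor drift/calibration error, compression lows,
or inter-day correlation beyond the shared diurnal profile. Passing
tests on synthetic panels therefore demonstrate the correctness of the
computations and the plumbing, not clinical validity on any real
population.

## Problem sizes

The test suite runs the full pipeline on simulated panels of 3–5
subjects at 3–14 days of 5-minute data, and checks each grid metric
against explicit double-loop oracles on 1000 random small grids (2–4
days × 24–48 columns) at 1e-9 absolute tolerance. These sizes exercise
every code path (gaps, day boundaries, missing blocks) while keeping
the whole suite under half a minute.

## Known limitations

- No excursion counting, day/night metric splits, or multiscale
  entropy.
- No native parsers for vendor export formats (Dexcom/Libre raw
  files); data must be pre-formatted to id/time/gl.
- Timezone changes (travel, DST) within a trace are not modeled; times
  are treated as local wall-clock throughout.
- MAGE's moving-average variant is a reasonable implementation of the
  crossing idea, not a validated clinical algorithm.
- J-index and GMI round-trips from *rounded* published summary
  statistics can disagree with published rounded metric values by one
  unit in the last digit; that is input rounding, not a computation
  property.
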