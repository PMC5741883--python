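# Methods

## Chill dose models

Both models are per-hour temperature weightings summed over a window of
hourly readings.

- **Chill hours (CH)**: indicator weight, 1 iff 0 °C ≤ T ≤ 7.2 °C.  The
  band endpoints are included; the bounds and inclusivity are model
  parameters (`ChillHourModel`).
- **Chill units (CU)**: weight 1 below 0 °C, the linear segment
  `−0.0605·T + 1` on [0, 10] °C (both endpoints evaluated by the linear
  segment, so `weight(10 °C) = 0.395`), and 0 above 10 °C
  (`ChillUnitModel`).  The weight is non-increasing in temperature and
  bounded in [0, 1], so a window's total never exceeds its hour count.

Windows are half-open `[start, end)` on hourly stamps.  This makes
accumulation additive over any partition and prevents double counting
when a transfer instant (9:00/10:00/11:00 in the experimental designs)
ends one window and starts another.  Totals are kept in full float
precision; `format_chill` applies 2-decimal half-up rounding at the
presentation layer only (840 h × 0.879 = 738.359… prints as 738.36).

Constant-temperature storage uses `hours × weight(T)`, which equals the
hourly sum on a constant series exactly; the equivalence is asserted to
1e−9 in the tests.

**Timestamps** are naive local clock time — weather-station records are
local readings, and no timezone or DST arithmetic is attempted.
**Missing hours** inside an accumulation window are a hard error that
lists the missing stamps, because a chill total is a plain sum and a
silent gap biases it low.  An opt-in interpolation mode fills gap runs
of at most 3 hours by linear interpolation in time.  Readings outside
[−30, 50] °C are rejected as sensor error at construction.

**Start rule.**  "The daily mean steadily passed the threshold" is
operationalized as the first date opening a run of `persistence_days`
(default 3) consecutive dates whose daily means are all strictly below
the threshold; the detected start is that date's midnight.  Three days
reproduces a unique start on smooth synthetic winters while a larger
window tolerates isolated warm days.  Because the original record's
start instants are partly ambiguous (a "12.00 a.m." clock time can be
read as midnight or noon), every accumulation entry point also accepts
an explicit start instant.

## CR brackets

A treatment is **adequate** when every configured rule holds for its
replicate-mean index value.  The default rule — final budbreak
percentage (FBP) ≥ 95 and at least one opening flower (NOF > 0) — is a
numeric stand-in for the original study's qualitative judgment, is
configurable, and is echoed into every report.

The bracket is `(L, U]` with `L` = largest dose among inadequate
treatments (open: that dose demonstrably failed) and `U` = smallest
adequate dose (closed: that dose demonstrably sufficed).  With no
inadequate treatment the lower bound is 0, closed.  No adequate
treatment at all means the CR exceeds the applied ladder and is an
error, not a bracket.  Non-monotone adequacy (an inadequate dose above
an adequate one, possible under noise) would invert the bounds and is
raised as an estimation error rather than silently reordered.
Intersection takes `[max lowers, min uppers]` with endpoint openness
propagated from whichever bracket supplied the binding endpoint, and is
commutative and idempotent; disjoint brackets return an empty result.

**Composite ranking** replaces the study's ANOVA-plus-judgment choice of
the optimal treatment (significance testing of morphology is out of
scope): per index, treatment means are min–max scaled across treatments,
flipped for lower-is-better indices (DEA, PAF, DFS, DFF in the shipped
registry), weighted (uniform by default) and averaged; ties break toward
the lower chill dose, since extra chilling is a cost.  Indices constant
across treatments carry no information and are dropped with a warning.

## Reverse use across winters

Given a CR value and a winter's checkpoint series (date → accumulated
chill, non-decreasing), the fulfillment date is the earliest checkpoint
whose accumulation reaches the CR — monotone in the CR by construction.
Cross-winter delay aligns dates on a July–June winter cycle so that
winters three years apart compare by month-day, and reports both
calendar days and days/7 rounded to the nearest whole week (the study
calls its 14-day checkpoint gap "2 weeks").  The packaged checkpoint
tables reproduce the published key-point totals by summation of the
printed per-interval values; the published Table values for Jan 21,
2013 differ between the treatment table (738 CH) and the key-point
table (795 CH) because their end-of-window conventions differ in an
unstated way, so each is reproduced only from its own printed inputs.

## Expression screening

The published screen ("genes with large differences in accumulation
between samples") states no numeric criterion, so the differential
filter is declared configuration: keep a gene iff
`(max + c) / (min + c) ≥ fold` and `max ≥ min_peak`, defaults fold = 4,
min_peak = 1 FPKM, pseudocount c = 0.1 FPKM.  The retained set is
invariant under sample-column permutation and under global rescaling
when the pseudocount and peak floor are rescaled with the data.

Keyword classification is case-insensitive substring matching over
description + homolog name, with separate temperature and photoperiod
phrase lists (disjointness enforced).  A dual match resolves to
temperature with a both-flag, mirroring the sequential order of the
original screen.  The shipped default lists extend the study's examples
("cold response", "heat shock", … / "photosystem", "circadian", …) and
are replaceable wholesale.

Heatmap standardization is a per-gene z-score with the population (n)
denominator, clipped to ±3; constant genes map to zero rows.  The ±3
scale reverse-engineers the published heatmap legend; the original
tool's exact formula (n vs n−1, clip rule) is undocumented, so the
choice is stated here rather than inferred.

qPCR uses **2^−ΔCt**, not 2^−ΔΔCt: the study defines no calibrator
sample, so expression is relative to the in-sample reference gene only
(a ribosomal-protein control chosen for stable transcription).
Technical triplicates are averaged on the Ct scale within each
biological replicate; each biological replicate yields one expression
value against its own reference mean; mean ± sd (ddof = 1) across
biological replicates is reported.  Technical spreads above 0.5 cycles
are flagged but not excluded.  Ct values outside (0, 45) are rejected.

## Congruence analysis

Profiles are compared by Pearson correlation at integer checkpoint lags
in [−max_lag, +max_lag], pairing `a[i]` with `b[i+L]` so a positive best
lag means the second winter's program ran late.  Six points is very
short for lag analysis: the overlap is kept at ≥ 3 points (max_lag ≤
length − 3), lags with a constant overlap are skipped (all skipped ⇒
degenerate-profile error), and the overlap size is reported.  Ties in r
(within 1e−9, absorbing float noise in the correlation) break toward the
smaller |lag| and then the negative lag — so a profile that correlates
equally everywhere (e.g. a pure ramp) reports no shift.

Typing thresholds are declared configuration, echoed in reports,
because the published three-way typing is verbal: **shifted_similar**
needs |lag| ≥ 1, r_best ≥ 0.8 and a gain r_best − r_zero ≥ 0.2 (the
gain requirement stops near-identical profiles from being called
shifted); otherwise **partially_similar** when max(r_zero, r_best) ≥
0.5; otherwise **dissimilar**.  A shifted-similar gene is
**CR-congruent** when |lag × spacing − delay| ≤ spacing, i.e. the
expression shift matches the fulfillment delay to within one checkpoint
interval; the irregular real sampling calendar (14–27 day gaps) is
summarized by its median spacing for this conversion.  An undefined
fulfillment delay propagates as not-evaluable rather than false.

## Synthetic data

`simulate_winter` builds T(t) = seasonal + diurnal + AR(1) noise +
warm offset on an hourly grid.  The seasonal term is a cosine with its
minimum at Jan 15 at `seasonal_mean` (default 4 °C) rising by
`2 × seasonal_amplitude` (default half-range 12 °C) toward summer; the
diurnal cosine (half-range 4 °C) peaks at 15:00 with its minimum
pre-dawn; the AR(1) noise has stationary sd `noise_sd` (1.5 °C) and
lag-1 correlation `ar1_rho` (0.8).  The defaults sketch a subtropical
winter of the kind the natural experiments ran in.  With `ar1_rho = 0`
the detrended series is white (lag-1 autocorrelation 0 ± 0.05 over
≥ 5000 h, tested).  A uniform `warm_offset` emulates a milder winter of
identical shape.

`simulate_morphology` gives each index a logistic dose-response in
accumulated chill: `baseline + (saturation − baseline) ·
logistic(k (chill − centre))`, replicate noise on top, lower-is-better
indices simply having saturation < baseline.  Two deliberate design
choices:

- the final-budbreak index is **anchored** so that it attains the 95 %
  adequacy threshold exactly at the planted requirement C*, which makes
  noiseless bracket recovery exact by construction rather than offset
  by the logistic's shoulder;
- the default steepness k = 0.1 per CH puts the 10–90 % transition at
  ≈ 44 CH, well inside one weekly dose step (168 CH).  A much flatter
  response leaves treatments near C* as adequacy coin flips under
  replicate noise and the bracket cannot be expected to contain C* at
  the tested ≥ 95 % rate; the transition sharpness is consistent with
  the one-step adequacy transitions visible in the study's budbreak
  ladders.

`simulate_expression_pair` plants three gene classes: CR-congruent
genes carry a unit Gaussian bump (sd 0.8 checkpoints) centred on each
winter's fulfillment checkpoint, so the planted lag is the checkpoint
difference; late-photoperiod genes ramp identically in both winters
(they track day length, not chill); fluctuating genes are uniform
noise.  Additive profile noise (sd 0.15) precedes FPKM scaling
(baseline 1, peak 50).  Ct tables derive target readings as reference
Ct − log2(relative expression) with cycle-scale noise (sd 0.2), so the
qPCR aggregation path is exercised on realistic raw readings.

The **two-winter scenario** used by the end-to-end checks simulates a
baseline winter and a +2 °C winter, samples both on six dates spaced 14
days from the colder winter's chill start, and selects a CR value for
which fulfillment falls exactly one checkpoint later in the warm winter
— the construction mirrored by the expression generator's planted
one-checkpoint lag.  A rare seed admits no such CR and is skipped (the
pipeline driver steps deterministically to the next workable seed).

What the generators do **not** emulate: real weather's synoptic fronts
and multi-day warm spells beyond AR(1) persistence, the irregular real
sampling calendar, overdispersed FPKM sampling noise, amplification
efficiency ≠ 2 in qPCR, and any correlation between morphology indices
beyond their shared dose-response.  Passing recovery tests therefore
demonstrate correctness of the estimation machinery under a clean
generative model, not performance guarantees on field data.

## Problem sizes and numerical choices

The seeded recovery checks use 200 dose-ladder scenarios (8 weekly
treatments each), 500 lag-recovery trials at noise sd 0.2, and 200
two-winter scenarios of 60 genes — sizes at which the binomial noise on
the tested rates is a small fraction of the margin to the thresholds
(≥ 95 % bracket containment, ≥ 90 % lag recovery, ≥ 90 %
sensitivity/specificity).  Accumulation equivalence is asserted to
1e−9; z-score moments to 1e−9; published chill constants to the printed
2 decimals.  Degenerate inputs (empty series, constant profiles,
all-missing Ct) raise typed errors rather than returning NaN.
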