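# Methods

`ncptkit` implements the data-processing pipeline behind a large web-based
cognitive assessment dataset: exclusion filtering of raw session logs, a
census-reweighted rank-based score normalization, a battery-level composite
index, normative tables, and a residual-correlation technical validation —
together with a synthetic-cohort generator that makes every stage testable
without any external data.

## The assessment and its data model

The NeuroCognitive Performance Test (NCPT) is a self-administered,
browser-based battery of brief cognitive subtests (go/no-go, memory span,
progressive matrices, trail making, ...). Eight standardized batteries
exist, each a fixed ordered set of 5–11 subtests; 17 distinct tasks appear
across them, several in two scored versions under distinct subtest ids.
Released scores travel in an 11-column CSV (one row per subtest score, with
the participant's age, gender, education code, country, battery/subtest
ids, hour of day, raw score, and the per-run Grand Index repeated on every
row of a test run). Normative tables use a 13-column CSV. `ncptkit.registry`
holds the fixed subtest/battery/education registries; `ncptkit.io` reads
and writes both schemas bit-exactly (full-precision numeric formatting, so
write-then-read is the identity).

Time-based exclusion rules cannot be expressed on the released score
schema, so the package defines a *session log* — per-subtest start/end
timestamps, trial events, and a pre-test gameplay count — as the input to
the filter stage. The simulator produces session logs; a pipeline fed bare
score tables skips the time-based filters with a recorded warning.

## Exclusion filters

A participant's data are excluded when

* the run is not the participant's first assessment (earliest subtest start
  wins; ties break on the lexicographically smaller run id so the result is
  independent of input order);
* any gap between one subtest's end and the next subtest's start exceeds
  24 hours (strictly — exactly 24 h is kept);
* another run started strictly inside the run's [first start, last end]
  interval (an interleaved assessment); a run starting exactly at the other
  run's last end is sequential;
* a trail making subtest (ids 39, 40) took longer than 15 minutes
  (strictly), in which case *all* of the user's data are dropped.

Gap endpoints (end-to-start) and the strictness of both thresholds are not
forced by the rules' prose; the choices here are documented and
configurable (`limit_s` arguments). The filters target disjoint defects, so
the surviving set is independent of application order; the implemented
order (interleave → first assessment → pause → trails) only determines
which reason a doubly-defective user is reported under. Ages over 89 are
top-coded to 90 (Safe-Harbor de-identification) after filtering.

## Census-reweighted inverse normal transformation

Participants are binned into K = 18 demographic cells: six age bins
([18–29], [30–39], [40–49], [50–59], [60–69], [70–99], boundaries
inclusive) × three educational-attainment bins ({some high school, high
school diploma/GED}, {some college, college degree, associate's degree},
{professional, master's, Ph.D.}). Education "Other" (code 99) and missing
education belong to no bin. A *reference composition* f\*₁..f\*₁₈ describes
the target population (in the intended use, census microdata; the package
ships a plausible census-like default and a uniform option — no joint
18-bin census table is published, only marginals, so the default is a
product of plausible marginals).

With sample bin proportions f_k and scores sorted ascending after
*orientation* (go/no-go and trail making scores negated so higher is always
better; released raw scores are never negated), observation i in bin k gets

    w_i  = f*_k / (N f_k)
    r~_i = w_i/2 + Σ_{j<i} w_j
    y_i  = Φ⁻¹(r~_i),   Φ⁻¹ the normal quantile at mean 100, SD 15.

When f\* = f this is exactly the textbook centered-rank INT,
r~ = (rank − ½)/N. When every reference bin occurs in the sample the widths
sum to 1 and every r~ lies strictly inside (0, 1); reference bins absent
from the sample lose their mass with a warning.

Numerical choices:

* **Ties.** The equations presume a strict order. Tied oriented scores
  receive the weight-averaged r~ of their tie group (the weighted midrank),
  so equal scores get equal normalized scores and the f\* = f reduction
  matches the textbook INT with average ranks exactly. An `ordinal` policy
  (stable-sort prefix ranks) is available behind a toggle.
* **Norm sample vs. everyone.** The transformation is *fitted* on the norm
  sample — participants with binnable age/education, at most 25 pre-test
  gameplays (when counts are available; otherwise that rule is skipped with
  a warning), and a complete battery. Everyone else is *mapped through* the
  fitted score → r~ curve by linear interpolation between adjacent sample
  points, clamped to [w_min/2, 1 − w_min/2] beyond the observed range. This
  makes normalization total without letting excluded participants influence
  the norms.
* **Version separation.** Scores from different versions of the same task
  (e.g. the two go/no-go ids) are normalized separately and never pooled;
  a given subtest id is pooled across batteries.

## Grand Index

The Grand Index (GI) of a complete test run is the mean of its normalized
subtest scores, re-mapped through a second census-reweighted INT to mean
100, SD 15. It is computed per battery (each battery's run means form one
sample), fitted on norm-sample runs and applied to every complete run;
incomplete runs have no GI. Because the second stage is rank-based, the GI
is invariant to the first stage's affine target, and both stages use
(100, 15). On a cohort whose composition matches the reference, the GI is
calibrated: mean ≈ 100 and SD ≈ 15 up to finite-sample error — the
acceptance suite checks this at n = 200,000 within three standard errors.

## Normative tables

Norms are computed on raw (unoriented) scores over the 18 demographic bins
further split by gender (36 cells), for participants with complete
demographics (gender in a configurable two-token set, default {m, f}).
For each battery, rows are emitted only if *every* (subtest × cell) —
Grand Index included — holds at least 20 participants; otherwise the whole
battery is omitted. Each row reports N, mean, SD, and the 10th/25th/50th/
75th/90th percentiles (linear interpolation between order statistics).
Percentiles follow the performance convention — a higher percentile is
better — so for time-scored subtests the p-th percentile column holds the
(100−p)-th raw-score quantile; the values themselves stay on the raw scale.

## Technical validation

Per battery and subtest, an OLS regression of the score on age (linear)
plus education and gender as categorical indicator sets is fitted on
participants with a complete battery and complete demographics (education
99 counts as complete here — the validation needs reported, not binnable,
demographics); residuals are the demographics-corrected scores. Pearson
correlations between subtests' residuals (listwise over complete runs) form
the per-battery correlation matrices, and `positive_manifold_check` passes
iff every off-diagonal entry is strictly positive. Scores are oriented
before residualization by default (a pure sign flip): the positive manifold
is the expected structure only in the higher-is-better direction, since raw
trail-making times necessarily anti-correlate with count scores. Levels of
a categorical observed exactly once are dropped with a warning; a singular
design raises.

## Synthetic cohorts

The generator's latent model is a single general factor: g ~ N(0, 1),
per-subtest ability a_s = λ_s·g + √(1−λ_s²)·ε_s + demographic effect, with
λ_s = 0.6 everywhere by default — giving ability-scale subtest-subtest
correlations of λ² = 0.36, comfortably inside the range reported for
cognitive batteries — plus a response-speed parameter loaded 0.3 on g.
Demographic effects on the ability scale default to −0.2 SD per decade of
age (centered at 45) and (−0.15, 0, +0.15) across the three education bins;
gender effects default to 0. The default cohort composition skews educated
and female with a few percent missing demographics, and the census-like
reference default is older and much heavier on high-school-or-less —
mirroring the qualitative sample-vs-census contrast such volunteer cohorts
show. Pre-test gameplay counts are lognormal with median 25, the median
reported for the real cohort (so roughly half the participants fall to the
norm-sample gameplay rule, as in the real pipeline).

Trial-level simulators (`ncptkit.simulate.tasks`) implement each task's
published stimulus structure, stopping rule and scoring rule exactly —
go/no-go stops at 5/10 correct go trials or 3 errors (three failed attempts
yield a missing score); the spans step their span every 2 or 3 trials and
end on two errors at one level; matrices and scale balance end on 3
consecutive errors; the Posner stimulus is cued on 60% of trials; timed
streams (arithmetic, grammar, digit symbol) fill 45/90 seconds; trail
making scores are sums of per-click response times with error-backtrack
penalties. The *agent* inside each task is an artifact choice: correctness
is Bernoulli(logistic(ability − difficulty)) and response times are
lognormal. Unpublished task parameters (the divided-visual-attention
staircase step of 100 ms with floor 100 ms / cap 3 s, span difficulty
slopes, item times) are package defaults, exposed in the code.

Cohort assembly administers the battery in order with 5–30 s gaps,
timestamps every subtest, and injects contamination per configured rates:
a >24 h gap, an interleaved second run (hosted inside a ~2 h within-limit
pause), an inflated >15 min trail making subtest, or mid-battery dropout.
Categories are assigned mutually exclusively so the truth table pairs each
contaminated user with exactly one exclusion reason, and the filter-recovery
tests can assert exact set equality. Everything is deterministic under
(config, seed).

Two generation paths exist. The trial-level path above is used at test
scale (hundreds to thousands of participants). For distributional
calibration at 10⁵+ participants, a vectorized score-level path
(`simulate_scores_fast`) draws raw scores directly from marginal models
that mirror the trial simulators (binomial counts, timed-stream counts,
lognormal times) under the same latent factor model; it produces no session
logs or contamination. The GI calibration and positive-manifold experiments
use this path: they exercise the norming and validation mathematics, which
consume only (score, demographics) pairs.

**What passing tests do and do not show.** The synthetic cohorts reproduce
the *structural* properties the pipeline relies on — schema, battery
compositions, a positive manifold, demographic main effects, missingness,
contamination — but not the real dataset's absolute score distributions,
its exact demographic counts, or training-related effects beyond a static
gameplay covariate. Results on synthetic data validate the machinery, not
any empirical claim about the real population.

## Problem sizes used in the shipped experiments

GI calibration: 200,000 participants (battery 39). Positive manifold: 100
seeds × 10,000 participants (battery 60). Factor-structure recovery:
50,000 participants. Filter recovery: 400 trial-level participants with all
contamination types. Posner cue-validity: 1,000 sessions × 100 trials.

## Known limitations

* The shipped census-like reference is a product of marginals, not a true
  joint table; real analyses should supply their own 18-bin composition.
* Session-log timestamps use an idealized continuous clock; no time zones,
  daylight saving, or client clock skew.
* The agent response model is not a cognitive model; simulated score
  distributions are plausible in range and ordering but not in shape.
* The pipeline holds all data in memory; it is comfortable at millions of
  rows but not engineered for out-of-core operation.
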