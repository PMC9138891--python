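# Methods

## The model

All eight behavioural and oculomotor measure series in this pipeline are
summarised with the exponentially modified Gaussian (ex-Gaussian)
distribution: the law of `X = N + E` where `N ~ Normal(mu, sigma^2)` and
`E ~ Exponential(tau)` are independent. Its density is

    f(x) = (1/tau) * exp(sigma^2 / (2 tau^2) - (x - mu)/tau)
                   * Phi((x - mu)/sigma - sigma/tau)

with `Phi` the standard normal CDF, and its first three moments are
`E[X] = mu + tau`, `Var[X] = sigma^2 + tau^2`, and skewness
`2 tau^3 / (sigma^2 + tau^2)^{3/2}` — strictly positive for `tau > 0` and
bounded above by 2. The interpretation that motivates the feature set:
`mu` and `sigma` describe the typical performance mode, while `tau` is the
mean of the slow right tail — rare prolonged observations usually read as
attentional lapses. Under growing cognitive workload, `tau`-type
parameters are expected to grow more than `mu`-type ones.

The density is evaluated entirely in log space
(`-log tau + (sigma/tau)^2/2 - (x-mu)/tau + log Phi(u)` via `log_ndtr`),
which keeps the product of an overflowing exponential and an underflowing
Gaussian CDF finite for `sigma/tau` ratios from 0.1 to 10 and beyond.

## Fitting

Maximum likelihood, minimising the negative log-likelihood with Nelder–Mead
simplex search over `(mu, log sigma, log tau)`; the log transform enforces
positivity without constraints. Settings: objective and parameter
tolerance `1e-8`, at most 2000 iterations. The start point is moment-based:
`tau0 = sd * (g1/2)^{1/3}` clipped to `[0.05 sd, 0.95 sd]` (the clip handles
non-positive sample skewness), `mu0 = mean - tau0`,
`sigma0 = sqrt(max(var - tau0^2, (0.05 sd)^2))`. Simplex search never
accepts an uphill step, so the fitted NLL is never worse than the start.

Degenerate inputs: series shorter than 5 observations raise a
`TooFewObservationsError` naming the threshold (the shortest series the
pipeline produces is a 10-s windowed count over a 90-s part — 9 values,
7 after trimming); zero-variance series raise a `DegenerateDataError`.
Windowed count series are discrete and are fitted with the continuous
likelihood, without a continuity correction. Non-convergence is flagged on
the `FitResult`, never silently discarded.

## The synthetic cohort

No recordings are distributed with this package; the generator emulates the
study design the analysis assumes: 30 subjects x 3 task parts (90 s with
4 symbols, 90 s with 9 symbols, 180 s with 9 symbols), i.e. three workload
levels and 90 sessions. Per session it produces a trial log (onset,
response time, correct flag; trials packed sequentially with a fixed 0.2-s
inter-trial gap) and an event stream in which fixations and saccades
alternate as a renewal sequence with independent ex-Gaussian durations,
saccade amplitudes are ex-Gaussian in degrees, and blinks form an
independent Poisson process whose events pause the fixation/saccade stream.
Timestamps are quantised to a 300-Hz clock (1/300 s) and printed at six
decimals, so files round-trip exactly.

Three nested sources of realistic variability:

- **Subject random effects** — one multiplicative lognormal factor per
  subject per measure (sd 0.08 on the log scale) applied to `mu` and `tau`,
  giving intra-subject consistency across the three levels.
- **Temporal drift** — a lognormal factor per 10-s block (sd 0.15 for
  oculomotor durations, sd 0.30 for manual response tempo) modelling
  time-on-task fluctuation. Without it, renewal-stream counts per 10-s
  window are nearly deterministic and small-integer count series (correct
  answers, blinks) collapse to a single repeated value, which the fitting
  layer rightly rejects. Manual tempo is allowed to fluctuate more than
  oculomotor micro-dynamics.
- **Accuracy fluctuation** — the per-block correct-answer probability moves
  on the logit scale (sd 1.0), modelling error bursts.

Even so, a count series can occasionally still collapse after trimming
(~1e-3 per session); drivers therefore retry a cohort draw with the next
derived seed a bounded number of times (`feature_table_for`), recording the
seed actually used. Within a fixed seed everything is reproducible: the
session for subject `i` at level `j` is seeded by
`SeedSequence([master_seed, i, j])` and subject effects by
`SeedSequence([master_seed, i])`.

Stock configurations (level order low/medium/high; times in seconds,
amplitudes in degrees):

- `default_workload_config` — the study-condition default. Response time
  `mu` 1.10/1.40/1.70 and `tau` 0.30/0.45/0.65; fixation duration `tau`
  0.100/0.130/0.165; saccade duration `tau` 0.008/0.014/0.022; saccade
  amplitude `tau` 1.5/1.9/2.4 with `mu` falling 3.5/3.3/3.1; correct-answer
  rate 0.95/0.88/0.80; blink rate 0.5/s at all levels. `tau`-dominant
  growth makes every temporal measure's skewness increase with level.
- `null_config` — all three levels share one generator and equal 90-s
  durations. Equal durations are deliberate: with unequal durations the
  windowed-count features have level-dependent estimator variance, a
  sample-size artifact that classifiers can exploit on a cohort meant to
  carry no class signal.
- `strongly_separated_config` — nearly non-overlapping level effects on
  response time, fixation/saccade dynamics, amplitude and accuracy; blink
  parameters constant, so blink features are a pure-noise negative control.
- `dominant_feature_config` — one dominant feature: response-time `tau`
  0.20/0.45/1.40 with everything else null or mild. The spacing is
  asymmetric on purpose: per-level weights come from one-vs-rest linear
  models, and a feature whose middle-class value sits midway between the
  outer classes is linearly invisible to the middle-class problem;
  asymmetric spacing keeps the feature informative for all three
  one-vs-rest problems. Mild fixation-duration and amplitude effects
  provide a moderate-importance tier so the three k-means clusters have
  substance at every level.

What the generator does **not** emulate: gaze coordinates, pupil size, raw
300-Hz samples, velocity-based event detection, sequential dependencies
beyond the block drift, device noise or data loss. Passing tests therefore
demonstrate that the pipeline recovers the structure this generative family
encodes — not that the original laboratory effect sizes are reproduced.
Real-data headline numbers (e.g. per-classifier accuracies) are not
comparable targets because the recordings are unavailable; the pipeline's
own cohorts yield qualitatively matching behaviour (random forest best,
above 95% on a well-separated cohort).

## Synchronisation and cleansing

Eye events and trials are merged by shifting both streams so the earlier of
the two first timestamps becomes 0; events at or beyond the session
duration are dropped with a logged count; disjoint time ranges are an
error. Cleansing removes exactly one highest and one lowest value from
each measure series of a session (first occurrence on ties — the rule reads
as single observations, not tied groups). Trimming is applied per series
after windowed counting and before fitting, so counts are computed on
complete streams; the alternative order (trim events before counting) is a
flagged sensitivity, not implemented.

## Features

Eight series per session: saccade amplitude, saccade duration, fixation
duration and single-trial response time from event rows; saccade, fixation,
blink and correct-answer counts over half-open 10-s windows `[10k, 10k+10)`
(9 windows for 90-s parts, 18 for the 180-s part; membership by onset,
for correct counts by trial onset). Each series is trimmed and fitted;
`mu` and `tau` of all eight measures enter the frozen 16-column schema,
`sigma` is computed and kept only as a diagnostic — the fixed discard rule,
applied unconditionally rather than re-decided per run. One row per
(subject, level): 90 rows under the default cohort.

## Screening

Per candidate feature (all 24 `mu`/`sigma`/`tau` columns, the sigma ones
diagnostically), the Friedman rank test with subjects as blocks and the
three levels as treatments: within-block average ranks,
`chi2_F = 12/(n k (k+1)) * sum_j R_j^2 - 3 n (k+1)`, referred to
`chi^2(k-1)`. The plain form is used without tie correction so the
all-tied design returns statistic 0 instead of an indeterminate ratio;
on tie-free data it agrees exactly with `scipy.stats.friedmanchisquare`.
With n = 30 blocks the chi-square reference is accurate (empirical type-I
error ~5% at alpha = 0.05). No multiple-testing correction is applied
across the 24 tests — the per-test alpha of 0.05 is the protocol — and the
report records the uncorrected count. Pairwise Spearman correlations
(average ranks on ties) over the 16 retained features flag
`|rho| >= 0.8` with `p < alpha` as strong; 0.8 is a declared convention,
configurable.

## Classification protocol

Three classes (low/medium/high), subject-independent: unique subjects are
split 80:20 (`|train| = round(0.8 n)`, 24/6 for 30 subjects) and all three
rows of a subject travel together; the absence of subject leakage is
asserted on every repeat. Features are z-scored with statistics from
training rows only for kNN, the SVMs, logistic regression and the MLP;
trees and forests see raw features. Each classifier is evaluated over 200
independent split/fit/score repeats (drivers use 50 to stay quick) and
summarised as mean (sd) of accuracy and macro-F1 across repeats.

The registry: decision tree (Gini, unlimited depth); kNN with k = 5; SVMs
with linear, quadratic and cubic kernels (C = 1, kernel coefficient
gamma = 1/16 — one over the number of features — polynomial kernels use
scikit-learn's homogeneous form with coef0 = 0); logistic regression with
elastic-net penalty (mixing 0.5, C = 1, saga solver); random forest with
100 Gini trees; MLP with two ReLU hidden layers (32, 16), at most 500
epochs, no early stopping. Macro-F1 averages the per-class F1 scores
unweighted. A repeat whose training partition misses a class is re-drawn
and counted (cannot occur with complete cohorts, guarded anyway).

On no-signal cohorts the expected accuracy is 1/3; any single cohort draw
fluctuates around it by several points (with 30 subjects, classifiers can
latch onto whichever chance pattern a majority of subjects shares — small-
sample optimism — while grouped splits can also push below chance), so
chance-level checks average over several independent null cohorts.

## Importance ranking

Per repeat (1000 by default, 100–200 in drivers and tests): draw a fresh
80:20 subject split, standardize the training portion on itself, fit a
3-class linear model — `LinearSVC` (C = 1) or one-vs-rest elastic-net
logistic regression — and take the per-class absolute coefficient vectors
as per-level weights, L2-normalised per repeat so every repeat contributes
equally. The per-level mean weights are grouped into high/medium/low by
1-D k-means with 3 clusters (50 restarts, tolerance 1e-10 — enough to hit
the contiguous optimum on 16 points, verified against an exhaustive
partition oracle in the tests), relabelled by descending cluster mean.
One-vs-rest is the default reading of "per-level weights from a 3-class
model"; a multinomial alternative is exposed for logistic regression. The
global ranking consumed by the accuracy-vs-feature-count curve is the
unweighted mean of the logistic-regression per-level weights.

## Problem sizes and numerical choices

Drivers and the acceptance script use reduced replicate counts — 50
classification repeats, 100–200 importance repeats, 3–5 cohort draws for
chance-level and noise-control rates — chosen so a complete run stays in
the single-digit minutes on one CPU while keeping Monte-Carlo error well
inside the tolerances being checked. Library defaults (200 / 1000) match
the full protocol. Grid-oracle comparisons use n = 40 samples against a
21 x 20 x 20 parameter grid; parameter-recovery checks use 100 replicates
at n = 1000. All randomness flows from explicit master seeds through
`numpy.random.SeedSequence` spawning.

## Known limitations

- Count series are modelled with a continuous likelihood; for means below
  ~2 events per window the discreteness bias on `sigma`/`tau` is material,
  which is one reason `sigma` is diagnostic-only.
- The generator's effect sizes are design choices, not estimates from the
  original recordings (no per-level summary tables exist to calibrate
  against); absolute accuracies on synthetic cohorts are therefore
  illustrative.
- Exact numerical equality with other ex-Gaussian fitters is not claimable
  (optimizer settings differ); agreement is to optimizer tolerance.
- The Friedman chi-square reference is asymptotic; for very few blocks
  (n <= 8) an exact enumeration would be preferable (the tests use hand
  values there).
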