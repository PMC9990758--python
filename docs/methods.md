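# Methods

`plrkit` implements a complete pupil light reflex (PLR) analysis
pipeline: a synthetic-recording generator with known ground truth,
signal conditioning and trial-validity screening, extraction of four
PLR metrics, and a two-group correlational/group-comparison statistical
plan. This note documents the models, the tunable parameters, the
numerical conventions, and the decisions taken where the design was
genuinely open.

## The task being modeled

Each trial lasts 6 s, sampled binocularly at 120 Hz (720 samples). A
fixation period of 1.6, 2.0, or 2.4 s (drawn uniformly per trial to
prevent anticipatory responses) precedes a 120 ms white flash; the
screen then returns to black for the remainder of the trial. The flash
elicits the PLR: a short-latency constriction from the baseline
diameter A0 toward a minimum A_m, followed by re-dilation. The initial
constriction phase is predominantly parasympathetic, which is why its
amplitude and latency serve as autonomic markers. Cohorts contain a
child group and an adult (college-age) group, each participant
completing nine trials and contributing three SRS-2 trait T-scores
(Total, SCI, RRB).

## Single-trial curve model

The noiseless diameter is a flat baseline followed by a bi-exponential
transient after a latency `L`:

    d(t) = A0                                    for t < L
    d(t) = A0 - (A0 - Am) * f(t - L)             for t >= L
    f(s) = (exp(-s/tau_r) - exp(-s/tau_c)) / f_peak

with constriction time constant `tau_c` < recovery time constant
`tau_r`, and `f_peak` chosen so the global minimum equals A_m exactly.
The defaults (`tau_c` = 150 ms, `tau_r` = 1500 ms, `L` ~ 235 ms) put
the diameter minimum near 600 ms post flash, comfortably inside the
1500 ms screening window. The velocity step at the latency kink gives
the acceleration series a sharp negative spike at constriction onset,
so the latency metric (argmin of acceleration) is recoverable to within
one or two samples. The curve family is a phenomenological stand-in for
the three-phase PLR, not a mechanistic (Edinger-Westphal) model; any
smooth family with a single post-flash minimum would serve, and this
one was chosen for its closed-form minimum.

Pupil units are millimeters (A0 ~ 3.5-7.5 mm across the cohort), the
native diameter unit of video-based eye trackers.

## Noise, blinks, and missing data

Measurement noise is white Gaussian per sample and independent between
eyes (default SD 0.05 mm). Blinks arrive as a Poisson process (default
1 per trial) with gap lengths uniform on 100-300 ms; a blink masks
*both* eyes (blinks are binocular) and masked samples are missing
(NaN), never zero-filled. These defaults were chosen once as plausible
for a cooperative but unconstrained participant; with them, an average
of roughly 6.8-7.1 of 9 trials per participant survive screening,
matching the usable-trial rate typical of this paradigm. The generator
does not model: trial-to-trial variability of a participant's PLR
parameters, pupil foreshortening from gaze angle, slow drift/hippus, or
luminance-dependent transfer — so passing tests demonstrate correctness
of the pipeline's bookkeeping and estimators, not robustness to every
artifact of real recordings.

## Cohort latent model

Per-participant parameters (A0, relative amplitude, latency) and
covariates (age, three trait T-scores) are drawn from a joint
latent-normal (Gaussian copula) model whose correlation matrix carries
the injected targets. The matrix is checked for positive
semi-definiteness at configuration time (minimum eigenvalue >= -1e-8)
and rejected otherwise. Marginals:

* Child age: truncated normal, mean 6.20, SD 2.68, range 2-12 y.
* Adult age: 18 + gamma matched to mean 20.34, SD 4.67 y. The heavy
  right tail occasionally produces participants in their late 30s/40s
  who are then removed by the 3-SD age-outlier rule — deliberately
  exercising that exclusion path.
* Trait T-scores: normal with mean 50, SD 10 (the T-score convention);
  trait-trait correlations default to Total-SCI 0.90, Total-RRB 0.75,
  SCI-RRB 0.50, reflecting that Total is a composite of the subscales.
* A0: child 5.5 +/- 0.8 mm, adult 4.64 +/- 0.8 mm; relative amplitude:
  child 0.36 +/- 0.07, adult 0.425 +/- 0.07; latency 235 +/- 30 ms in
  both groups. These group means make the ground-truth child-vs-adult
  effects d ~ 1.07 for baseline and d ~ 0.93 for relative amplitude
  while leaving latency and absolute amplitude with essentially no
  group difference.
* Default injected correlations: adult RRB with relative amplitude
  -0.36 and with latency +0.32, Total with relative amplitude -0.28 and
  latency +0.21, SCI with relative amplitude -0.21; child age with A0
  +0.31 and RRB with A0 -0.32; relative amplitude with latency -0.40
  (adult) / -0.20 (child).

A_m is derived as `A0 * sqrt(1 - rel_amp)`. Parameters are clipped to
physical ranges (A0 >= 1 mm, rel_amp in [0.02, 0.90], latency in
[60, 480] ms); at the default means these clips are > 4 SD away and do
not measurably attenuate the injected correlations (verified by the
Monte-Carlo recovery checks: mean sample r over 500 replicate n = 66
cohorts lands within 0.01 of the -0.36 target).

Each participant's nine trials share the participant's parameters;
within-participant variation comes only from noise, blinks, and the
randomized fixation duration.

## Screening

Stage 1, on raw samples (per eye per trial):

1. at most 100 ms of missing data — i.e. at most 12 samples at 120 Hz,
   inclusive, counted as *total* (not consecutive) missing samples —
   in the half-open window (flash, flash + 1500 ms];
2. a valid sample at flash onset itself.

Stage 2, after smoothing: the diameter minimum, the most-negative
velocity, and the most-negative acceleration over (flash, 1500 ms]
must occur within 1500, 750, and 500 ms of the flash respectively
(earliest index on ties). Because the literal diameter argmin over the
search window is trivially inside it, the first criterion is read as
"the minimum is *attained* in the window": an argmin pinned to the
window edge while the series is still decreasing fails. A search window
truncated by the trace end, or still containing unresolved missing
samples, fails with a `window_incomplete` flag.

Gap handling between the stages: missing runs of <= 12 samples are
linearly interpolated anywhere; runs intersecting the metric region
(200 ms pre-flash baseline window through the 1500 ms QC window) are
interpolated regardless of length, since stage 1 has already bounded
the post-flash missingness and the pre-flash diameter is
quasi-stationary; longer runs wholly outside that region stay missing
and are excluded from all search windows. Runs touching a trace
boundary are filled by nearest-value extension and flagged.

## Smoothing

The cleaned diameter series is filtered with a degree-2 Savitzky-Golay
filter, window 11 samples, producing smoothed diameter (derivative
order 0), velocity (order 1), and acceleration (order 2); each series
is then convolved with a discretized, renormalized Gaussian kernel of
SD 5 samples. Conventions:

* Velocity is computed even though only diameter and acceleration
  series are strictly needed for the metrics, because the 750 ms
  screening criterion is defined on velocity.
* SG derivative outputs are divided by dt^order so velocity and
  acceleration are per-second; screening uses argmin *locations* only,
  so the scaling cannot change pass/fail.
* Edges use mirror padding for both filters. The trial edges are
  > 1.5 s away from every metric window, so the edge policy cannot
  affect metrics (exercised by the end-to-end tests).
* The Gaussian kernel is truncated at 4 SD (radius 20 samples) and
  renormalized to unit sum.
* The Gaussian stage is applied to all three series; applying it to
  the derivative series as well as the diameter is a documented choice
  where the processing description is ambiguous.

## Metrics

* A0: mean smoothed diameter over the 200 ms window ending at
  (exclusive of) the flash sample. The window length is a configurable
  default; "just before the flash" admits any short window.
* A_m and its time: minimum smoothed diameter over (flash, 1500 ms],
  so the metric and QC definitions coincide.
* Relative constriction amplitude: (A0^2 - A_m^2) / A0^2
  (dimensionless, in [0, 1] for a true constriction). A_m > A0
  (paradoxical dilation) yields a negative value and flags the trial
  but does not exclude it — exclusion would be an undocumented extra
  filter.
* Absolute constriction amplitude: A0 - A_m (mm).
* Constriction latency: time from flash *onset* (not offset) to the
  argmin of smoothed acceleration within (flash, 500 ms]. A flat
  acceleration window (no constriction, e.g. a constant trace) raises
  a degenerate-trial error and invalidates the trial rather than
  returning a spurious 0.

Eyes are combined per trial by arithmetic mean when both are valid
(per-eye extraction first, then averaging); a single valid eye is
carried forward with a `single_eye` flag. Participants aggregate over
valid trials — means for A0 and the two amplitudes, the median for
latency — and are included only with >= 4 valid trials; excluded
participants carry no aggregates.

## Statistics

* Age outliers: within each group, participants more than 3 sample SDs
  from the group age mean are excluded, in a single pass (mean and SD
  from the full group, no re-computation); "more than" is strict, so a
  value exactly at 3 SD stays.
* Children use first-order partial correlations controlling for age
  (df = n - 3); adults use bivariate Pearson correlations (df = n - 2).
  The partial correlation uses the closed-form
  `(r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))`; the test suite
  verifies it against residual-regression and pingouin oracles.
* Bonferroni families: 6 comparisons among the four PLR metrics
  (critical p = 0.05/6 = 0.0083), 4 comparisons per trait scale
  (critical p = 0.05/4 = 0.0125), and 4 group-comparison t-tests
  (critical p = 0.0125).
* Group comparisons use pooled-variance Student's t (df =
  n_A + n_B - 2) with Cohen's d computed from the pooled SD; the sign
  convention is adult minus child.
* All p-values are two-sided. Correlations use pairwise-complete
  observations and every result records its effective n, so df can
  legitimately differ across tests within a family. Results with
  p < 0.10 that miss their corrected threshold are labeled trends and
  never counted as significant.

## Problem sizes and reproducibility

The analysis scripts and the acceptance script use a full-size cohort
(65 children, 77 adults, nine trials); Monte-Carlo validation uses 500
replicate n = 66 cohorts for correlation recovery and power, 1000 for
the null family-wise error rate, and 200 simulated participants for
metric parameter recovery — sizes at which Monte-Carlo standard errors
(about 0.005 on a mean r, 0.007 on an FWER) are well below the margins
being tested. Every stochastic component draws from a
`numpy.random.Generator`; identical configuration plus seed reproduces
output tables bit-for-bit, and simulating with noise or blinks but
without a seed is an error rather than a silent nondeterminism.

## Known limitations

* The simulator's trait scores are continuous; real SRS-2 T-scores are
  integers with floor/ceiling effects.
* Per-participant PLR parameters are constant across trials, so
  trial-scatter of the metrics reflects only noise and smoothing — the
  parameter-recovery tolerances would need widening under true
  trial-to-trial physiological variability.
* The latency marker inherits a systematic half-sample to one-sample
  bias from discretizing the constriction-onset kink; at 120 Hz this
  is ~8 ms, well inside the +/- 3 sample recovery tolerance, but it is
  a bias, not noise.
* The exclusion ledger assigns each failed eye-trial to its *first*
  failing criterion (missing > at-flash > min > velocity >
  acceleration), so category counts are unambiguous but not additive
  across overlapping failure modes.
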