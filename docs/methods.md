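# Methods

`pupilmath` implements an analysis pipeline for pupillometry studies of
mental arithmetic and math anxiety (MA): a synthetic cohort generator that
emulates the study's data, the trace preprocessing chain, a crossvalidated
mixed-model timecourse analysis, and BIC-based best-subset modelling of the
link between pupil features, task performance, and anxiety questionnaires.
This note records the models, their assumptions, and the design choices
made where the design was genuinely open.

## Task design

A session presents 24 spoken multiplication problems (multiplicand 12–14;
multiplier 6–9 for *easy*, 16–19 for *hard*), each repeated three times, in
a seeded random permutation: 72 experimental trials preceded by 4 practice
trials (2 easy, 2 hard) and split into two contiguous blocks of 36. The
first part of a trial is a 750 ms baseline, an auditory difficulty cue
opening a 4000 ms anticipation window, three 750 ms sounds, and a 6000 ms
no-response window, i.e. a fixed 13 000 ms before the earliest allowed
response; the response then ends the first part at a variable time. The
second part re-baselines for 750 ms, plays a 750 ms confirmation sound
(4000 ms wait window), then a 750 ms feedback sound (4000 ms feedback
window), followed by a uniform 750–1250 ms inter-trial interval. Open
choices fixed here: blocks are contiguous halves; the permutation is
unconstrained; cues always match the problem's difficulty.

## Synthetic cohort

### Between-participant structure

Six observed measures are coupled through a Gaussian copula: the AMAS
(math anxiety, 9 items, 1–5), TAI (test anxiety, 20 items, 1–4), STAI
trait-anxiety (20 items, 1–4), PMP (mathematical competence, 30 binary
items), task accuracy, and pupil peak latency. Latent traits are drawn
from a multivariate normal and mapped monotonically to each scale:
Likert items load on their trait with the inter-item correlation implied
by the target Cronbach's alpha (0.89/0.93/0.90), PMP items are probit
threshold indicators (difficulty spread so the total averages ≈ 24.6),
accuracy uses per-difficulty logistic links centred on 90% (easy) and 61%
(hard), and latency is linear in the trait (8.9 ± 3.0 s easy, 15.5 ± 6.4 s
hard, clipped to [2, 28] s).

Because item aggregation, rounding, and nonlinear links attenuate Pearson
correlations, the copula uses *disattenuated* latent correlations:
target(i,j) / sqrt(rel_i · rel_j), with per-measure reliabilities (0.89,
0.93, 0.90, 0.85, 0.94, 0.97) frozen after a single Monte-Carlo
calibration at n = 50 000; observed scores then recover the targets to
within 0.02 (0.03 at n = 5000, the tested tolerance). The default target
matrix pins the AMAS row (r with TAI .41, STAI .23, PMP −.30, accuracy
−.36, latency .48) and the TAI/STAI–latency couplings (.42/.14); remaining
pairs are plausible fixed values for a university-student population, and
the full matrix is verified positive semi-definite (latent minimum
eigenvalue 0.27). Non-PSD user matrices are rejected naming the offending
eigenvalue.

### Trace model

A trial's 500 Hz pupil trace is tonic baseline + evoked dilation + noise,
in arbitrary eye-tracker units (baseline ~N(4000, 600²) across
participants). The evoked component is a gamma-density kernel (shape 3)
starting at calculation onset, peaking at the participant's per-difficulty
expected latency (±5% trial jitter) with amplitude 300 a.u. (×1.35 for
hard problems, ×lognormal(0, 0.1) jitter); hard cues add a small (60 a.u.)
anticipatory bump after the cue, and incorrect feedback adds a 120 a.u.
bump in the feedback phase. Noise has two components: a fast AR(1)
(φ = 0.995 at 2 ms, stationary sd ≈ 20 a.u.) and a slow tonic drift
(Ornstein–Uhlenbeck, time constant 20 s, sd 60 a.u.) representing the
low-frequency arousal/hippus band — without the slow component the
baseline-alignment and baseline-rejection stages would have nothing to
correct. Blinks arrive as a Poisson process (0.15 /s), 100–400 ms of
tracker-invalid samples flanked by partial-occlusion edge samples with
large sample-to-sample velocity. Response time is the expected peak
latency plus 0.5–2.5 s, floored at the 6000 ms minimum window. A
`null_cohort` switch replaces all trait- and difficulty-dependent kernel
parameters with common constants, giving a cohort with no pupil couplings
for type-I-error calibration. Per-participant RNG streams derive
deterministically from the root seed.

What the generator does *not* emulate: gaze position, the pupillary light
reflex and luminance (the paradigm is auditory with a constant display),
foreshortening, trial-order effects (fatigue, learning), and any
within-participant trait variability beyond the modelled jitters. Passing
tests therefore demonstrate correctness of the *pipeline* under the
assumed generative family, not fidelity to any particular real dataset.

### Epoched-scale generator

Monte-Carlo studies of the timecourse analysis use a direct generator of
binned, z-scale pupil values on the analysis grid (participant intercept +
trial offset + windowed effect bumps + AR noise across bins). Its default
variance decomposition — trial offset sd 0.28, within-trial sd 0.23 with
lag-1.5 s autocorrelation 0.35, participant sd 0.2 — was measured from the
raw-trace pipeline's baseline-aligned binned residuals on a null cohort,
so the cheap simulations mirror the primary generator.

## Preprocessing

The chain is: (1) artifact detection — tracker-flagged blinks plus samples
adjoining a first difference deviating from the median velocity by more
than k·MAD (default k = 16, configurable; the threshold is a robust scale
rule because blink edges are tens of MADs out), every artifact run
extended by 100 ms per side; (2) trial rejection if the masked fraction
strictly exceeds 40%; (3) linear interpolation of remaining gaps, flat at
the edges; (4) cubic smoothing-spline low-pass filtering (penalty 0.01 on
time in seconds: gain ≈ 1.0 at 0.5 Hz, ≤ 0.11 at 4 Hz and above); (5)
median downsampling to 25 ms bins; (6) z-transform per participant over
all binned samples of their kept trials; (7) per-part baseline alignment
by subtracting the mean of the initial 750 ms window (a fully missing
first-part baseline rejects the trial); (8) rejection of trials whose
baseline lies outside ±2 SD of the participant's baseline distribution
(computed per participant, sample SD; a zero-SD set rejects nothing).
Each trial's two parts are processed on separate clocks throughout.

Trial features: maximum dilation relative to the aligned baseline and its
latency, searched from the offset of the second number to the end of the
first part, with latency in seconds from that offset; the tonic baseline
is the mean raw (arbitrary-unit) pupil in the first fixation window.
Participant values are grand averages over kept trials. At the default
artifact settings the synthetic cohort discards ≈ 4–6% of trials per
participant.

## Crossvalidated timecourse analysis

Per-timepoint models are random-intercept LMMs (one intercept per
participant, no random slopes), fit by maximum likelihood by default (REML
by flag) through a dedicated profiled-likelihood solver: with a single
random intercept the covariance per participant is I + λJ, so the
deviance profiles to a one-dimensional search in λ and one fit costs
O(N p²). Satterthwaite (fractional) degrees of freedom are computed from
the observed information of the variance components, with a residual-df
fallback at the λ = 0 boundary and normal-approximation p-values always
exposed; the solver reproduces lme4/lmerTest estimates, t values, and
Satterthwaite dfs to three significant figures on test problems.

Covariate codings: the difficulty cue is sum-coded (−0.5 easy, +0.5 hard),
trial-level accuracy is centred 0/1, continuous covariates are z-scored;
interactions are products of coded terms.

The crossvalidated procedure assigns each participant's kept trials to 3
folds deterministically (rank mod 3); for each rotation, models at every
timepoint on the two training folds yield per-effect |t| profiles; each
effect's peak-|t| timepoint is selected, and the left-out fold's trials
contribute their pupil value there. After three rotations every trial
carries one value per effect, and one final mixed model per effect
(same fixed-effects formula) gives the reported t/df/p. Consensus
clusters are maximal runs of timepoints where all rotations exceed
|t| > 2, optionally confirmed by a mixed model on the within-window mean.
A liberal per-timepoint scan (no multiplicity correction) reports each
effect's minimum p and its location. The common grid runs to the 90th
percentile of first-part durations by default; shorter trials are simply
missing at late timepoints.

### Calibration of the final test

Null-cohort simulation (20 participants × 24 trials, 13-point grid, 2000
replicates) puts the final cue test's rejection rate at α = .05 at
7.6% ± 0.6 — mildly anticonservative. The mechanism: the three rotations'
training sets overlap, so each fold's data helps select the timepoints at
which the *other* folds are evaluated, making the fold-wise spurious
contrasts positively dependent and inflating the pooled statistic's
variance by ~10–15% (sd of the null t ≈ 1.12). The inflation grows with
the number of effectively independent timepoints in the grid and vanishes
if each rotation's selection uses a single disjoint training fold.
Between-participant effects (questionnaire scores) are driven by
participant-level noise that is common to all timepoints, so selection
does not inflate them; they calibrate at ≈ 5% under REML, while ML shows
the familiar small-sample anticonservatism at 20 participants (≈ 7%),
which shrinks as the cohort grows. Practical guidance: treat final
p-values near .05 for within-participant effects with caution, prefer
REML for small cohorts, and rely on the consensus clusters (which require
all rotations to agree) for localisation. Power is excellent: an injected
cue effect of 0.3 z in a 6 s window is detected with the correct sign in
> 95% of replicates, with selected timepoints inside the true window.

## Feature model selection

Anxiety outcomes are z-scored (n−1 sd) before modelling; the five
predictors (accuracy rate, PMP, baseline pupil, max dilation, peak
latency) stay on their native scales. All 2^p subsets are fit by least
squares and ranked by BIC = −2 log L̂ + k ln n with the maximum-likelihood
error variance and k = #predictors + 2 (intercept and variance counted);
under this convention the intercept-only BIC on a z-scored outcome depends
only on n (206.14 at n = 70), which pins the convention. Bayes factors are
exp(ΔBIC/2). Leave-one-subject-out cv-R² uses the full-sample mean in the
denominator and is floored at 0 for reporting (the raw value is also
returned). Note the exhaustive search's inherent false-inclusion rate:
each spurious candidate enters the best subset with probability
≈ 2Φ(−√ln n) (≈ 3.9% at n = 70), so exact-set recovery degrades
geometrically with the number of noise candidates even at high
signal-to-noise.

The power module computes the noncentral-F power of testing u
coefficients with f² = partial R²/(1 − partial R²) and noncentrality
λ = f²(u + v + 1) (Cohen's convention; λ = f²n selectable, and the two
coincide when v = n − u − 1). Monte-Carlo regression simulations reproduce
the curve to ±0.01.

## Psychometrics

Pearson correlations carry exact-t p-values and Fisher-z confidence
intervals tanh(atanh r ± z·/√(n−3)); perfect correlations return the
degenerate interval. Paired difficulty contrasts use the classical paired
t (df = n−1). Cronbach's alpha is k/(k−1)(1 − Σ item var / total var).
Descriptives report bias-uncorrected moment skew and excess kurtosis
(switchable in principle via scipy options). The MA/accuracy clustering
is best-of-50-restarts k-means (k = 2) on standardized features with a
fixed seed; a median-split labeller exists for plotting only — inference
is parametric throughout.

## Problem sizes and numerical choices

Simulation-backed tests use scaled-down designs chosen to estimate each
property with adequate Monte-Carlo precision: 500 null replicates at
20 × 24 for type-I error, 100 replicates for power, n = 5000 for copula
recovery, 1000 replicates for best-subset recovery. Peak selection breaks
ties toward the earlier timepoint (`argmax`). Singular per-timepoint fits
are skipped and logged; trials missing at a timepoint drop from that fit.
All analyses are pure functions of (data, config, seed); config files
reject unknown keys and every output bundle embeds the config hash.
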