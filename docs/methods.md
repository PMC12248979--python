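# Methods

This note documents the models, algorithms and calibration choices behind
`fixfill`, and what the synthetic test bench does and does not establish
about real data.

## Scope and data model

The package analyses trials of a fixation / filling-in task: a participant
fixates while a colour boundary of a given contrast (DKL azimuth difference,
10/20/30°) and eccentricity (2/4/6° disk radius) fades, and presses a key at
complete filling-in. The filling-in time (FT) is the fixation duration up to
the press; the trial times out at 20 s. Gaze is binocular at 1000 Hz, in
degrees of visual angle relative to the fixation point; samples inside
blinks are invalid. Monocular events are out of scope: detection is strictly
binocular, and all derived positions use the two-eye mean.

## Microsaccade detection

Velocity is estimated per eye and axis as the slope of a centred
least-squares line over a 31-ms window. This estimator is exact for linear
motion and attenuates the sharp peak of a real saccade profile (a ~0.5°
event with a 30 deg/s analytic peak reads back near 21 deg/s); amplitudes
are measured from position, not velocity, and are unaffected. The centred
window also *anticipates* onsets by roughly 6–8 ms, since samples ahead of
the onset already contain ballistic motion; detected onsets are therefore
expected within ~10 ms of truth rather than sample-exact.

The noise scale per axis is the median-based robust SD
σ = √(median(v²) − median(v)²) over defined samples (≈ 0.6745 × the Gaussian
SD for white noise), and the threshold is η = λσ with λ = 5 (per-participant
override supported, e.g. λ = 6 for noisy recordings). A sample is a
candidate when (vx/ηx)² + (vy/ηy)² > 1 **in both eyes simultaneously** — the
intersection rule, chosen over union-then-verify as the stricter reading of
binocular detection. Runs of ≥ 8 candidate samples form events; events
separated by < 12 ms merge (idempotently); events whose binocular-mean
movement direction turns faster than 15°/ms are discarded (direction is
treated as undefined below 0.5 deg/s, where it is numerically meaningless);
events overlapping blink-padded regions cannot occur because padded samples
are undefined by construction.

Amplitude is the Euclidean norm of the per-axis max–min bounding box of the
binocular mean trajectory during the event — robust to curved paths, unlike
start-to-end displacement. Events below 3 arcmin are classified as
drift/noise; events above 2° amplitude, or with a median binocular speed
above 30 deg/s, are returned in a separate large-saccade list so exclusion
logic can use them rather than losing them silently.

## Trial metrics

**Retinal slip** (ocular drift): the binocular mean path is quantized to a
0.01° × 0.01° grid (about a cone's receptive field). For each 50-ms segment
with no invalid sample and no sample within 10 ms of a microsaccade, the
number of *distinct* cells visited, minus one, times the cell size, divided
by the segment's time span, is a drift speed; the trial value is the mean
over valid segments. A stationary eye yields exactly 0 (hence count − 1),
and a straight 1 deg/s drift is recovered up to the one-cell quantization of
a segment (±0.2 deg/s). Slip is averaged over the whole trial; no
sub-window is used.

**Exclusions**, in fixed precedence order (the order is a reproducibility
choice; ties are impossible since the first violated rule reports):
FT < 2 s; median binocular displacement from fixation > 1°; a blink within
300 ms before the press; a large saccade within 300 ms before the press.

**Immobilization time** is press time minus the last microsaccade offset,
defined only when that interval exceeds 300 ms (later events are plausibly
motor-related rather than perceptual). **ms_rate** divides the event count
by the full FT; blink-masked time is not subtracted (a simplicity choice,
documented rather than hidden).

## Rate dynamics

The report-aligned rate uses the causal kernel ω(τ) = α²τe^(−ατ), α = 1/100
per ms, truncated at 1001 ms and renormalized to unit integral on a 1-ms
grid, so the estimate at t depends only on onsets at or before t. Trials
contribute to the denominator only at times they span, which removes edge
bias from unequal trial lengths. Baseline is the arithmetic mean rate over
−5 to −3 s before the press; per-participant curves are scaled
multiplicatively so each baseline equals the grand mean (zero-baseline
participants are omitted and reported).

## Mixed models and inference

All three outcomes (FT, trial-wise microsaccade rate, immobilization time)
are natural-log transformed. Continuous predictors (contrast, eccentricity,
trial number, blink count, ocular drift, last-event amplitude) are
standardized by zero-centring and dividing by the population SD over the
fitted trials; binary microsaccade presence stays 0/1. Interactions are
products of the (standardized) parents. Models are fitted by REML through
statsmodels' MixedLM with a per-participant random intercept and the
specified random slopes as *independent variance components*. A fully
correlated six-dimensional random-effect covariance is fragile with ~20
participants; fixed effects — the inferential targets — are robust to this
simplification, which is the package's deliberate structural choice.

Optimization tries the default gradient-based optimizer and falls back to
Powell whenever the fit does not converge or is degenerate (flagged when the
residual variance exceeds the data variance — the signature of a silently
failed profile optimization). Non-convergence is always flagged on the
result, never silently accepted.

Inference uses the participant-level case bootstrap: whole participants are
resampled with replacement (relabelled uniquely so duplicates remain
distinct grouping units), the model is refitted, and fixed effects are
recorded. Percentile CIs are taken at the Bonferroni-corrected level α/k
(k = non-intercept fixed effects: 99.5% intervals for the 10-term primary
model, 98.33% for the 3–4-term models), with tail quantiles rounded outward
to order statistics — conservative at modest resample counts, where
interpolated tails run narrow. The default is 500 iterations at desk scale;
10,000 is available by argument. More than 20% non-converged iterations
aborts with a diagnostic.

Term retention compares BIC with and without each candidate term using
**ML** (not REML) fits, since REML likelihoods are not comparable across
fixed-effect structures; a term is removed only if removal lowers BIC, and a
main effect never leaves while an interaction it parents remains. Subset
models split blink-free trials by microsaccade presence, downsample the
larger subset per participant to match the smaller (the smaller subset is
never altered), and fit random-intercept-only models with uncorrected 95%
intervals. Eccentricity can be replaced by its cortical-magnification
transform d = ln(E)/0.063 − 36.54 mm (0 mm at 10° eccentricity) via a flag.

## The synthetic generator

The generator emulates the study conditions: 21 participants × 9 blocks
(3 contrasts × 3 eccentricities, order randomized per participant) × 40
trials, 1000 Hz, with these components:

- **Drift**: a conjugate 2-D random walk. The diffusion default
  (4 × 10⁻⁴ deg²/s) is set so the retinal-slip metric, computed on the raw
  binocular path, lands in the physiological 0.5–1 deg/s band.
- **Microsaccades**: raised-cosine velocity profiles with peak velocity =
  main-sequence slope (60 (deg/s)/deg) × amplitude. Requiring the profile to
  displace the eye by exactly its amplitude fixes the duration at
  2/slope ≈ 33 ms for all amplitudes; an amplitude-dependent duration is
  geometrically incompatible with holding both the main sequence and the
  displacement, and those two are the properties the analyses rely on.
  Amplitudes are log-normal (median 20 arcmin, log-SD 0.7) truncated to
  [3 arcmin, 1.5°]. Directions are error-correcting: once cumulative
  saccadic displacement exceeds 0.2°, directions bias back toward fixation
  (±60° jitter), keeping gaze bounded as real fixation is; uniform
  directions would random-walk away from the fixation point and trip the
  displacement exclusion.
- **Event counts**: drawn before the outcome, over a nominal duration equal
  to the model-implied mean FT, from a gamma-Poisson mixture (shape 1.3).
  The overdispersion produces the realistic ~10% of trials with no events at
  a 0.89 Hz mean rate — a homogeneous Poisson process would make presence
  nearly constant (~99.9%) and the presence coefficient unidentifiable — and
  drawing counts first breaks the circular dependency between microsaccade
  presence (a covariate) and trial duration (the outcome).
- **Outcome**: log FT = offset + Xβ + Zb + ε, with independent normal random
  effects per participant (default SDs 0.2 intercept, 0.05 per slope) and
  residual SD 0.3. The published coefficients live on a standardized scale;
  the offset maps that scale onto seconds so the mean FT matches the
  observed 7.51 s, accounting for the non-centred binary presence covariate
  and the log-normal mean correction. Trials below the 2-s floor redraw
  their residual (so generated data pass the short-trial filter; this binds
  < 1% of trials and biases coefficients by ≤ 2%); trials beyond the 20-s
  timeout are *capped in duration* while the latent outcome is preserved —
  redrawing at the cap would truncate the outcome distribution and
  measurably attenuate the injected coefficients, defeating parameter
  recovery.
- **Dip**: events scheduled in the final 600 ms before the press are
  relocated earlier with probability 0.8, reproducing the pre-report rate
  suppression that the causal-rate analysis should recover.
- **Blinks**: 100–300 ms invalid gaps at 0.1 Hz, placed uniformly.

Determinism: one seed fixes every draw; identical configuration and seed
give bit-identical traces and tables.

### What the generator does not emulate

Measurement noise defaults to 0.1 arcmin per sample — far below video
eye-tracker noise — because the slip metric operates on the raw gaze path,
where realistic white noise would dominate grid traversal. The generator
therefore models an effectively denoised signal; detector recall and slip
values on real, noisier recordings will be worse than the synthetic results
show. Drift is a plain random walk (not self-avoiding or mean-reverting),
saccade durations do not scale with amplitude, and the perceptual process
itself is represented only through the outcome regression, not
mechanistically. Passing tests demonstrate the correctness of the analysis
chain, not the validity of the scientific model on real recordings.

## Parameter recovery and problem sizes

The recovery studies (`fixfill.recovery`, `scripts/acceptance.py`) inject
the published fixed effects as ground truth, re-fit, and average recovered
coefficients over 10 replicates at full design size (7,560 trials; 630 for
the subset model). Per replicate, the recovered coefficient equals the
injected value plus the sample mean of that term's random slopes
(SD 0.05/√21 ≈ 0.011) plus estimation noise; the replicate mean is expected
within ~0.01 of truth. Test tolerances use two Monte-Carlo SEs over the
replicates with an absolute floor of 0.02, the scale of the printed
three-decimal precision. The test suite runs reduced-scale versions of the
heavier simulations (e.g. 80-resample bootstraps, 20-replicate coverage
studies at 21 participants × 8 trials) to stay within a few minutes of
runtime; the acceptance script runs the full recovery in under a minute.
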