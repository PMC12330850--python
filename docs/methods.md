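# Methods

This note documents the models, algorithms and numerical choices behind
`ssvepgen`, in the spirit of a package reference: what is computed, under
which assumptions, and where the design was genuinely open.

## The experimental design being modelled

The pipeline targets a cue-in-context threat-generalization paradigm.
Gabor patches at eight orientations (CS+ = +45°; −45°, +15°…+75° as
generalization stimuli) flicker at 7.5 Hz for 4 s per trial.  An
acquisition phase presents 18 trials per orientation, with the CS+
reinforced on 100% of trials by an aversive stimulus at cue offset.  A
context phase repeats the same trial structure inside six aversive and six
neutral picture blocks of 24 cues each (again 18 trials per orientation and
context).  Trial order is pseudo-randomized with no more than three
identical orientations in a row; ISIs are 2–3 s and each block begins 5–7 s
before its first cue, so a block lasts roughly 160 s.  Measures are
129-channel EEG (500 Hz), pupil diameter (60 Hz) and 0–100 US-expectancy
ratings.

## Synthetic cohorts

`synth.GenParams` holds the generative model.  Its defaults are the
package's reference study conditions and are not tuned per analysis:

* **ssVEP signal.**  Per trial, during cue-on time,
  `a1·cos(2π·7.5·t + φ1) + a2·cos(2π·15·t + φ2)`, time-locked to cue
  onset.  The fundamental amplitude `a1 = a1_base + a1_context_offset`
  in aversive blocks (1.0 + 0.3 µV); the harmonic
  `a2 = a2_base + a2_gradient_peak·exp(−Δθ²/2w²)` carries a Gaussian
  generalization gradient over orientation distance from the CS+
  (0.8 + 0.5 µV, w = 15°).  This implements, as the generative truth, the
  dissociation the analysis is designed to detect: contexts modulate the
  fundamental, cues the second harmonic.  Phases default to 0 (the analysis
  is phase-blind); the generator emits sinusoids at the two analysed
  frequencies rather than simulating square-wave retinal transduction,
  because only those two bins enter the analysis.
* **Topography.**  A von-Mises-like kernel `exp(κ(cosγ − 1))` about the
  centroid of the occipital pool (κ = 8), giving occipitally maximal
  activity.  No generative topography is implied by the phenomenon itself;
  this is a minimal smooth choice.
* **Noise.**  1/f^α background noise (α = 1), 15 µV RMS per sensor,
  synthesized by spectrally shaping white Gaussian noise with an exact
  variance normalization.  The 15 µV default makes raw single trials look
  like EEG (the ~1 µV ssVEP is invisible before averaging) and puts
  condition-average occipital SNRs in the 2–10 range typical of published
  ssVEP data.  Subject-level variability is a log-normal amplitude gain
  (σ = 0.2).
* **Pupil.**  Event-related dilation with a smooth 1 s rise to plateau;
  amplitude = 0.15 mm × the same Gaussian orientation tuning + 0.05 mm in
  aversive blocks + a subject intercept (0.08 mm) + per-trial amplitude
  noise (0.35 mm, the dominant variance source in real pupillometry) +
  small per-sample noise.  Blinks arrive as a Poisson process (0.2 Hz) and
  mask 100–300 ms of samples.
* **Ratings.**  base 10 + 60 × tuning + 5 in aversive contexts + subject
  intercept (σ = 8) + noise (σ = 10), clipped to [0, 100].

What the generator does **not** emulate: oscillatory alpha structure,
non-stationary drift, eye/muscle artifact waveforms (artifacts are injected
separately as labelled spikes/drifts/flatlines for screening tests),
volume-conduction mixing beyond the smooth topography, binocular
disparity, or learning dynamics across trials.  Passing tests therefore
demonstrate that the analysis recovers effects of the assumed form at
realistic amplitude/noise ratios — not that it is robust to every artifact
structure of real recordings.

Determinism: every generator draws from `default_rng([seed, subject_id,
stream_tag])`, so outputs are bit-reproducible per (seed, subject) and
independent across stages.

## Schedules

Orientation orders are blockwise-balanced (three per orientation per
24-trial block) and rejection-resampled until the concatenated
presentation order — including across block boundaries — contains no run of
four identical orientations.  Failure after `max_attempts` raises; the
constraint is never silently relaxed.  ISIs and lead-ins are uniform on the
printed ranges (the distribution is not specified by the design; uniform is
the maximum-entropy choice).  Trials per cell is configurable (default 18;
scaled-down cohorts use 6) with block counts scaling to keep 24-cue blocks.

## EEG preprocessing

* Epochs: −600…+3900 ms at 500 Hz (2250 samples); the last 100 ms of the
  4 s cue is excluded by construction so reinforcement never contaminates
  the analysed window.
* Low-pass: zero-phase (forward–backward) Butterworth at 40 Hz.  The
  printed description of the original filter ("45 dB/octave, 23rd-order
  Butterworth") is internally inconsistent — a 23rd-order Butterworth rolls
  off far steeper than 45 dB/octave — so the order is a parameter
  (default 4, which after the forward–backward pass attenuates ≥ 40 dB at
  twice the cutoff; verified against the analytic magnitude response).
* Artifact screening (SCADS-style): per (trial, sensor) the absolute
  maximum, standard deviation, and maximum successive difference are
  robust-z scored (median/MAD, with MAD = 0 handled exactly: identical
  values score 0, deviants infinity) against their distributions over
  trials within each sensor *and* over sensors within each trial; a cell is
  flagged if any |z| > 3 in either comparison.  Trials with > 20 flagged
  sensors are rejected; remaining flags are spherical-spline interpolated
  (order m = 4) from unflagged sensors.  The original tool's exact
  distribution limits are not recoverable from its description, so all
  thresholds are explicit parameters; the "statistical weighting" of
  interpolated values defaults to plain spline interpolation.
* Averaging: arithmetic mean per subject × condition over retained trials;
  empty expected cells are recorded.  For acquisition-phase learning
  analyses, trials are split into first/second halves by presentation order
  (odd counts: the first half takes the extra trial); a participant is
  excluded from that analysis iff any orientation × half cell is empty
  after rejection.

## CSD and spectral analysis

The surface Laplacian uses spherical splines: G and H matrices from
Legendre series of inter-sensor cosines (m = 4, 50 terms — standard values
from the spherical-spline literature), G regularized by λ = 0.2 on the
diagonal (the dense-array recommendation), spline coefficients solved per
time sample under a zero-sum constraint, output projected through H.  The
operator is precomputed as a single matrix, making the transform exactly
linear; a constant map yields zero CSD and a degree-2 spherical harmonic is
an eigenfunction (sign preserved), both under test.

The FFT window is 600–3900 ms post-onset, truncated to the largest whole
number of 7.5 Hz cycles (3200 ms), so the bin width is 0.3125 Hz and
7.5/15 Hz fall exactly on bins 24/48 — the neighbour-bin SNR formula
requires exact alignment, and the 3300 ms printed window does not align at
500 Hz.  Spectra are mean-detrended, and power is normalized so a
unit-amplitude bin-aligned sinusoid yields 1.0 in its bin.  SNR at a target
bin is its power divided by the mean of six neighbours, read symmetrically
as offsets ±2, ±3, ±4 (skipping the immediate neighbours ±1); both counts
are parameters.  SNR is computed on subject-level condition averages
(evoked power), then pooled as the arithmetic mean over Oz + 7 neighbours
(EGI 70, 71, 72, 74, 75, 76, 82, 83).  Positions for the 129-channel
reference layout come from MNE's bundled montage, projected to the unit
sphere.

## Pupil pipeline

Linear interpolation of blink/tracking gaps (edge gaps: nearest-valid
extension; all-missing trials are dropped and reported), zero-phase 2 Hz
Butterworth (order 2; no filter family is implied by the measure, and a
gentle low-order filter avoids ringing at 60 Hz), baseline subtraction of
the −500…0 ms mean, and the 500–4000 ms mean change as the scalar
response.  Binocular averaging is a pass-through hook (`average_eyes`);
the generator emits an already-averaged trace.  An optional
max-missing-fraction trial filter exists but is off by default, since no
exclusion criterion is implied by the design.

## Inference

Within-subject ANOVA is computed from sums of squares with the classical
subject-cell decomposition; each multi-level effect's degrees of freedom
are multiplied by Greenhouse–Geisser epsilon computed from the covariance
of its orthonormal-contrast scores (Huynh–Feldt behind a flag; two-level
effects have ε = 1 identically).  GG is the default because the reported
fractional dfs imply some sphericity correction and GG is the field (and
afex) default.  Partial eta-squared comes from the sums-of-squares ratio,
which equals F·df1/(F·df1 + df2) in these designs; its 95% CI inverts the
noncentral-F distribution for the noncentrality λ and maps
λ/(λ + df1 + df2 + 1), pinned at 0 when F is inside the central tail.

Paired t-tests report Cohen's d for difference scores, d = t/√n — the
convention that reproduces every printed (t, d) pair; the pooled-SD
convention does not.  The d interval inverts the noncentral-t distribution
at the 2.5/97.5 points and divides by √n (scipy's far-tail NaNs are
replaced by their asymptotic limits before root-finding).

## JZS Bayes factors

Candidate cue patterns are fixed zero-sum weight vectors over the seven
orientations +15°…+75° (the −45° control is outside the weight models):
sharpening (difference of Gaussians) = (+0.5, −1, −2, +5, −2, −1, +0.5)
and generalization (quadratic trend) = (−3, +0.5, +1.5, +2, +1.5, +0.5,
−3).  Each candidate linear mixed model — weight score and context
indicator (centered ±0.5; centered coding keeps BFs coding-invariant in
the balanced design) as fixed effects, subjects as random intercepts — is
compared against the random-intercepts-only null.  The context model uses
the context indicator as sole fixed effect.

Priors are Zellner–Siow: standardized fixed slopes share one variance
multiplier g₁ with mixing density InverseGamma(1/2, r²/2), r = 0.5 (the
scale mixture that makes each slope marginally Cauchy(0.5)); random
intercepts get their own g₂ with r = 1; Jeffreys priors on the grand mean
and error variance.  Sharing a single g across the fixed effects (rather
than one per term) keeps the integral two-dimensional; it is this
package's documented choice of "default" prior.  Conditional on (g₁, g₂)
the marginal likelihood is closed-form; the Woodbury identity reduces each
evaluation to a k×k Cholesky (k = fixed + subjects), batched over the
whole quadrature grid.  Each g axis is mapped to (0, π/2) by
g = r²·tan²ψ and integrated with tensor Gauss–Legendre (64 nodes per
axis); a halved-order recomputation must agree within 1e−4 relative (or
1e−5 absolute) on the log scale or the call raises — there is no silent
fallback.  A Monte-Carlo integrator over the same prior is provided as a
cross-check mode, and the one-predictor case reproduces the textbook JZS
regression integral to ~1e−12.  Natural-log BFs are reported per sensor,
frequency and model; per-sensor failures become NaN entries rather than
aborting a topography.

## Power simulation

The pre-registered design question is read as: condition means (0, d·SD)
with common SD and correlation ρ between conditions — i.e. d is a
raw-scale standardized mean difference, not a difference-score dz.  Only
this reading yields ≥ 80% power at n = 50 with d = 0.30, SD = 1.4,
ρ = 0.80 (the dz reading gives ≈ 55%), and it matches d, SD and ρ being
listed as separate quantities.  Each replicate draws n bivariate-normal
pairs and applies a two-sided paired t-test; the Monte-Carlo proportion is
validated against the closed-form noncentral-t power with
dz = d/√(2(1−ρ)).

## Problem sizes used in the shipped checks

The package's own verification runs use scaled cohorts chosen to exercise
every stage with comfortable margins: the end-to-end parameter-recovery
check uses 20 subjects at 6 trials per orientation × context cell on the
full 129-channel layout (retention ≈ 99.9%, context effect at 7.5 Hz with
F(1,19) ≈ 21, cue effect at 15 Hz with F(7,133) ≈ 8.5, pool-level log BFs
≈ +8 for context@7.5 Hz and ≈ +10.5 for generalization@15 Hz); unit tests
use 48-sensor quasi-uniform layouts and 3–9 trials per cell.  The power
simulation always runs at the full 5000 replicates.

## Known limitations

* SCADS parameters approximate a procedure whose exact original settings
  are not published; flags on clean data run at a few percent (they are
  interpolated, not rejected), which slightly smooths topographies.
* The shared-g JZS prior differs from implementations that assign one g
  per model term; BFs agree in order of magnitude but not to the digit.
* The Greenhouse–Geisser ε of a two-way design is estimated per effect
  from its own contrast covariance; with few subjects ε estimates are
  noisy, as in any rmANOVA software.
* The generator's effects are additive and Gaussian-tuned by construction;
  it cannot produce interactive cue × context structure, so tests of the
  interaction term only ever check correct null behaviour.
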