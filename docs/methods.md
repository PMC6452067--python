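# Methods

`sonarcee` implements the analysis chain of a multi-scale controlled exposure
experiment (CEE) on deep-diving odontocetes: a tagged focal whale, several
satellite-tagged whales and a moored passive-acoustic recorder observe the
same sonar transmission at different spatio-temporal scales. Because CEE
field recordings are not publicly deposited, the package pairs every analysis
stage with a synthetic-data generator that produces inputs with known ground
truth; all tests and the acceptance script run against those.

## Synthetic data

**Transmission schedules.** Two protocols are built in. The *close*
treatment transmits 1.0–2.0 kHz hyperbolic-upsweep pulses of 1 s every 20 s
(duty cycle 5%) for 15 min at full power with no ramp-up; a reduced-output
variant (`close-low`) transmits the same timing at 122 dB source level. The
*distant* treatment transmits a 3.4–3.9 kHz compound tonal (500 ms linear
upsweep 3350–3450 Hz, then 500 ms tones at 3600 and 3900 Hz) of 1.5 s every
25 s (duty cycle 6%), with a 20 min ramp-up rising linearly in dB from 154 to
214 dB re 1 µPa² m² followed by 15 min at full power.

**Biologging records.** The dive generator is a parametric phase machine
(descent / bottom foraging / ascent / surface / shallow bout), not a
mechanistic model: only the statistical contrast between baseline behaviour
and the avoidance phenotype matters downstream. Baseline cycles alternate
deep foraging dives (default 800 m, ~1.6 m/s descent, 15 min of bottom
foraging with annotated click trains and buzzes) with shallow-diving bouts.
No quantitative species-typical dive parameters are asserted; every duration
and rate is configurable. After the response onset (exposure start plus a
configurable delay) the simulated whale switches to sustained avoidance:
constant heading with very low circular variance, elevated speed (default
gain 1.7), shallow directed travel, and no foraging sounds. Accelerometer
and magnetometer channels are synthesized from the attitude sequence
(aerospace z-y-x Euler convention, NED Earth frame, high-latitude magnetic
field), so the orientation estimator can be validated by round-trip.
Flow-noise band level is a monotone linear function of speed plus noise.

**Satellite tracks.** Hourly positions follow a 3-state Markov chain with
gamma step lengths and von Mises turn angles; multinomial-logit transition
probabilities out of state 1 respond to the time-to-recovery covariate (and
optionally its product with standardized SPLmax). Observation noise is
isotropic Gaussian (error-ellipse structure is out of scope); a configurable
fraction of fixes is missing, and planted outlier fixes (40 km displacement
in one hour, guaranteed clean neighbours) exercise the speed filter.

**PAM scenes.** In `psd` mode the generator emits framed power spectral
densities directly: exponential per-bin noise (the single-frame periodogram
statistic of Gaussian noise), click energy added to the 20–40 kHz band of the
frame containing each Poisson-distributed click, and optional guard-band
(4–8 kHz) or broadband interferers. The frequency axis is decimated (default
every 32nd bin) because the detector only uses band integrals; this keeps
hour-scale scenes memory-light. `audio` mode synthesizes a pressure waveform
(white noise plus 0.4 ms Hann-windowed 30 kHz tone bursts) for tests of the
spectral front end itself. What the scenes do *not* emulate: realistic click
spectra and directionality, propagation-shaped noise spectra, and overlapping
whale groups — so detector results on them demonstrate correctness of the
statistic, not field performance.

**Determinism.** Every generator consumes one seeded
`numpy.random.Generator`; identical seeds give bit-identical arrays. The
pipeline driver fans a master seed out to per-stage seeds by fixed offsets.

## Tag features

Seven 5 Hz variables are derived per record. Pitch/roll come from the
gravity direction, heading from the tilt-corrected magnetic vector
(clockwise from geographic north; declination is a configuration input).
Depth is an affine pressure map with a linear temperature term. Speed
through water inverts a monotone flow-noise-level calibration and is defined
only at depth > 5 m. Depth inflections are the proportion of sign changes of
the first-differenced depth in a 30 s window; circular variances of heading
and pitch use a 1 min window; ODBA averages the summed absolute dynamic
acceleration over 5 s, with gravity separated by a running mean of the same
length (the most common convention; configurable). "Pitching movement" has
no canonical definition; it is implemented as the magnitude of high-pass
filtered pitch rate (zero-phase 2nd-order Butterworth, default cutoff
0.125 Hz ≈ half the nominal fluke-stroke frequency) and the cutoff is
exposed. All windows are centred and require full support: edges and windows
containing masked samples are masked, which keeps window means unbiased.
Per-pulse received SPL is the maximum over the pulse of the 200 ms sliding
RMS level (dB re 1 µPa), reported together with the whole-pulse RMS level
and their difference (the averaging-time correction).

## Mahalanobis change-point detection

Windows of 15 min at 1 min steps are averaged per variable (two default
variable sets: *avoidance* = speed, heading circular variance, depth, depth
inflections; *locomotion* = ODBA, pitching movement, pitch circular variance
— artifact defaults, fully configurable). The baseline mean and covariance
come from the pre-exposure window vectors; the MD is evaluated in
per-variable standardized space (exactly equivalent by affine invariance but
stable when variable scales differ by orders of magnitude), with a ridge of
1e-6 · trace/dim added to the correlation matrix only when its condition
number exceeds 1e8. The detection threshold is the 95th percentile of maxima
of resampled baseline stretches of length equal to the analysis horizon;
*block* mode (default) resamples contiguous circular blocks, preserving the
strong autocorrelation of overlapping windows, while *single* mode draws
windows independently. The change-point is the earliest window centred at or
after the exposure start with MD at or above the threshold; sample-level
onset refinement (done by expert panels in the field workflow) is out of
scope, so the full MD series is returned for review.

**Calibration.** The construction is designed so that an exposure-free
record crosses the threshold with probability ~5% over the horizon. This
holds asymptotically; at short baselines it degrades for two reasons we
quantified during development: the overlapping windows leave only ~B/15
effective degrees of freedom for the covariance (inflating out-of-sample
MDs), and the threshold is a noisy tail quantile (exceedance is convex in
the threshold, so its noise inflates the false-alarm rate). The packaged
calibration study (`null_false_alarm_rate`) therefore uses conditions where
these nuisance effects are negligible: per-minute Gaussian feature summaries
rolled into 15-min windows (reproducing the overlap autocorrelation at the
analysis-unit scale, which is why 1000 records run in seconds), a 48 h
baseline, a 35-min horizon (one exposure duration) and single-window
resampling, whose maxima stochastically dominate those of correlated
stretches and keep the threshold mildly conservative. A known limitation
follows: with a field-realistic ~4 h baseline the same construction is
markedly anticonservative, so field change-points near the threshold should
be interpreted with care.

## Response-intensity model

Behaviour is binned into non-overlapping 35 min bins (the longest exposure
duration), aligned to the exposure start for exposed whales, and each bin's
MD is computed against the pooled average baseline behaviour of all whales.
The expected MD of whale *i* in bin *k* is

    RI_ik = β₀ + β₁ L_i · exp(β₂ (τ_i − t_ik)) · (1 + β₃ R_i)   if t_ik ≥ τ_i
    RI_ik = β₀                                                   otherwise

with L_i the received SPLmax offset by 79 dB re 1 µPa (a beaked-whale
hearing-threshold reference, so L = 0 means "inaudible"), R_i the minimum
source distance (km) and τ_i the exposure bin. β₂ ≥ 0 gives exponential
decay of the effect after exposure (with the exponent written on τ − t, the
decay parameter is non-negative; the constraint can be disabled). Observed
MDs are gamma with shape ω and scale RI/ω, so RI is the mean. The model
family is the full model plus seven reductions — level term β₁L replaced by
a single parameter γ, decay dropped, distance dropped, in all combinations —
compared by AIC; an intercept-only specification (no exposure effect) is
additionally available because null simulations need it as a candidate.
Baseline whales' bins enter the likelihood with mean β₀.

Fitting maximizes the gamma log-likelihood by L-BFGS-B on log-transformed
positive parameters (β₀, ω, β₁ or γ, β₂; β₃ free with a positivity barrier
on the predicted mean) from up to 16 deterministic multi-starts, tolerance
1e-8. Non-positive MDs are floored at half the smallest positive value
(gamma support) and counted. Standard errors come from the inverse numerical
Hessian at the MLE in natural parameter space. Identifiability: with the
level term reduced to γ and the distance term retained, γ and β₃ trade off
along a ridge; the Hessian-based covariance exposes the resulting flatness.

The recovery/ranking simulation study uses 4 exposed + 10 baseline whales
with ~10 bins each, ω = 4, and an exposure design spanning a wide range of
received levels (SPLmax 99–134 dB re 1 µPa) with distances decorrelated from
levels — the contrast the close/distant treatments were built to create.
With levels clustered or correlated with distance, β₁L and the γ reductions
are near-indistinguishable at this sample size and no "strong level effect"
exists to detect.

## Movement HMM

Raw fixes pass an iterative 8 m/s great-circle speed filter (a fix is
removed when the implied speeds to both neighbours exceed the threshold),
then are linearly interpolated onto the hourly grid (gaps > 3 h left
missing; a state-space track filter is deliberately out of scope). Step
lengths are great-circle distances (km) on the WGS84 mean sphere; turn
angles are signed bearing changes, positive for a left turn; intervals
adjacent to missing positions are missing.

The 3-state HMM uses gamma step lengths and von Mises turn angles (turn
means free by default, optionally fixed at 0). State step means are
parameterized as ordered increments, so state 1 is always the
shortest-step (tortuous) state and no post-hoc relabelling is needed; this
also pins the covariate structure, which enters only the multinomial-logit
transitions out of state 1 (candidate models: no covariates;
time-to-recovery; its interaction with standardized SPLmax; its interaction
with standardized source distance — per-track scalars are z-scored and the
scaling reported). Time to recovery decays linearly from 8 h at the exposure
time-step to zero and is zero before exposure. All tracks share one
transition model; missing observations contribute unit likelihood while
transitions advance; the initial distribution is the stationary distribution
of the covariate-free transition matrix.

The forward log-likelihood (numba-compiled scaled recursion) is maximized
directly by L-BFGS-B from a moment-based start plus seeded jitters —
simpler than EM for covariate-dependent transitions. Candidate models are
ranked by AIC and the *simplest model within ΔAIC < 2* is selected; Viterbi
decoding (ties toward the lower state index) yields state sequences, and a
leave-one/two-out refit loop reports selection stability against
non-independent individuals. Four-state models are out of scope.

The planted-effect study (9 tracks × 96 hourly steps, exposure at 48 h)
uses a tortuous-dominant baseline transition matrix, matching the
observation that whales forage (state 1) before exposure. This matters for
power: the covariate acts only on transitions out of state 1 during the 8 h
recovery window, so with uniform occupancy a track contributes only ~3
informative transitions and no strong effect is expressible.

## PAM detector and click-absence test

Audio is framed into Hann-windowed, 50%-overlap, one-sided PSDs with density
scaling (integrating the PSD over frequency recovers the frame power
exactly; validated by a Parseval check). The frame is 8192 samples at the
144 kHz default rate (56.9 ms); other rates use round(0.0569 · fs). Frames
are normalized by a noise floor: the time average of the frames whose mean
5–50 kHz level lies in the lowest 5% — rare loud transients cannot enter the
floor. Per 2.5-min segment (grid anchored at the recording start, partial
trailing segment dropped) and per band (echolocation 20–40 kHz, guard
4–8 kHz), the statistic is the time average of the loudest 1% of per-frame
band-integrated normalized levels; "loudest 1% of frames per band" was
chosen over a per-bin variant (retained as a config option) because it
yields one robust scalar per band and is insensitive to isolated bins. A
click detection is scored when echo minus guard level meets the threshold
(5 and 8 dB are the conventional operating points); broadband transients
raise both bands and cancel — the purpose of the guard band. Because the
statistic is self-normalized, a constant gain on the whole recording leaves
it unchanged. With the default exponential noise model the noise-only
difference sits slightly below 0 dB (the narrower guard band has noisier
top quantiles), well clear of the operating thresholds.

Maximal runs of non-detected segments form click-absent periods; runs
≤ 10 min are excluded from the baseline (such gaps occur naturally during
foraging). The response test compares the last absent period starting
during the exposure against the 95th percentile (empirical, type-7
interpolation — one rule named for reproducibility) of the baseline
durations, reporting the empirical percentile and a low-power flag when
fewer than 20 baseline periods exist.

## Acoustic dose

The propagation model is spherical spreading plus linear seawater absorption
(Thorp's formula at the band centre by default, overridable):
SPL = SL − 20 log₁₀(r/1 m) − α·r_km, with r the 3-D slant range and ranges
clamped at the 1 m reference. This is a deliberately simple, pluggable
stand-in — the substantive machinery is the Monte-Carlo propagation of
uncertainty around it. Per draw, the animal's horizontal position (isotropic
Gaussian) and depth (normal, with separate surface/diving uncertainty
distributions fitted by moment matching to dive-summary-vs-coarse-depth
residuals) are sampled; per pulse, the SPL plus the averaging-time
correction (mean 200 ms-minus-whole-pulse difference from paired tag
measurements) is computed. Summaries are per-pulse medians with 5–95%
intervals and the SPLmax (per-draw maximum over pulses) with a 90% interval.
For unlocalized animals near a mooring, positions are drawn uniformly over
the 1–4 km detection annulus and depths resampled from pre-exposure tag
data. The draw count (default 1000; ≥ 100 enforced) and all uncertainty
inputs are recorded in the estimate metadata. An optional cosine-taper
elevation gain stands in for the source's vertical beam pattern (off by
default); full-field acoustic modelling and hearing-weighted levels are out
of scope.

## Pipeline and reporting

`run_experiment` executes simulate → features → change-point → dose → RI
comparison → HMM → PAM from one master seed and writes a JSON/CSV report.
SPL at onset is the maximum pulse SPL received up to and including the
change-point window; the onset is flagged *censored* (an upper bound) when
the onset resolution exceeds the pulse interval (coarse tags) or the
exposure had no ramp-up, mirroring how close-treatment thresholds are
left-censored. Report invariants: an onset SPL is present exactly when a
change-point exists.

## Problem sizes and limitations

Test and acceptance runs use desk-scale sizes chosen as the package's own
defaults: 10 h tag records at 5 Hz, 1000 calibration records, 100 RI
replicates (9 candidate models each), 50 HMM selection replicates (9 × 96
steps), hour-scale PAM scenes in PSD mode. Known limitations: the generators
omit social correlation between whales, bathymetry, error-ellipse Argos
structure and realistic click spectra; the change-point threshold is
anticonservative at short baselines (above); the propagation stand-in
ignores refraction and multipath, so absolute dose values are only as good
as spherical spreading; and passing tests demonstrate correctness of the
statistics on data matching the generators' assumptions, not field
performance.
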