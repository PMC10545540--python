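# Methods

This note documents the models, conventions and numerical choices behind
`photoline`, in the order data flows through the package. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Acquisition model and re-binning

A raw session is a 4 kHz record of multiplexed fluorescence, a binary
illumination-select waveform (470-nm vs 405-nm excitation, switching every
10 ms = 40 samples, aligned to the 100 Hz output grid), treadmill velocity
(forward positive), a binary lick trace and stimulus delivery times.
Each 40-sample illumination epoch yields one value for the channel that was
lit: the mean of its **central 15 samples**, dropping the transition samples
symmetrically at both ends of the epoch (the LED settling time; symmetric
placement is chosen for phase neutrality, since only the count of dropped
samples is physically constrained). The channel that was dark during a
given 10-ms bin takes the value of its nearest own-channel epoch
(sample-and-hold, ties to the earlier epoch), so both channels are full
100 Hz traces of `floor(duration × 100)` bins. Velocity and licking are
averaged (licking: max) over all 40 samples per bin. A trailing partial
epoch is discarded rather than averaged from fewer samples. Event times are
stored in seconds; bin assignment everywhere uses half-open bins
[k/100, (k+1)/100).

## ΔF/F normalization

Per channel, independently:

1. `F_bg = F − 0.85 · P8(F, 20 s)` — background-light correction. `P8` is
   the centred running 8th percentile over a 20-s window, truncated at the
   trace edges, with numpy's linear-interpolation percentile definition.
   0.85 is the background share of baseline fluorescence (a fixed constant,
   exposed as `qc.BACKGROUND_FRACTION`).
2. `F_bg / P8(F_bg, 20 s)`, expressed in percent — removes photobleaching
   and slow drift.
3. Zeroing: the 470 trace is offset so the **median of its non-transient
   bins** is 0 (non-transient = outside every detected transient's
   [rise-start, decay-end] span); the 405 trace by the median of all bins.
4. Comparison scale: both channels are multiplied by
   `100 / (largest detected 470 transient peak)`, so the largest transient
   peaks at 100. If no transient is detectable the scale falls back to the
   trace maximum and a warning is recorded on the `DffRecording`.

The running percentile is computed exactly (not approximated): interior
bins by an in-place sliding sorted window (one memmove per step), edge bins
by incremental insertion into a growing sorted prefix/suffix. Both are
oracle-tested against brute force.

Two properties worth knowing. (a) Because a constant multiplies out of
every step, the output is invariant to positive rescaling of the raw
fluorescence. (b) Percentile baseline-tracking is mildly nonlinear in
transient density: with ~0.4 transients/s the running 8th percentile climbs
onto transient skirts and the recovered response integrals sit ~5–7% below
the generative values; the truncated edge windows also degrade within one
window length (20 s) of the trace ends, where a fast-bleaching session can
show a few percent of residual drift. Both effects are inherent to the
procedure, not bugs, and bound the realistic recovery accuracy.

## Transient detection and QC

Transient detection removes slow fluctuations by subtracting the running
8th percentile over 250 bins (2.5 s, two-to-three transient widths), smooths
over 0.2 s, and segments the trace at the zero-crossings of its 0.2-s
smoothed derivative. A segment qualifies as an isolated transient if its
rise exceeds **30 ΔF/F s⁻¹** and the immediately following decay reaches
**−5 ΔF/F s⁻¹** ("decay greater than −5" is read as slope ≤ −5). The peak
is located on the smoothed trace and refined on the unsmoothed trace within
±0.05 s — exact for a clean transient, and less skewed toward the slow
decay side under noise than a raw argmax. "Smoothed" always means a
centred moving average of the stated width with truncated edge windows.

SNR = (80th percentile of transient peak amplitudes) / s.d.(trace − its
0.1-s moving average); the gate is **strictly** SNR > 10, plus ≥ 0.2
transients/s. Noiseless synthetic input floors the noise at 1e−12 and flags
the result.

Artifact exclusion uses only the 405 channel: `maxnoise` = max |405 −
0.1-s moving average|; bins beyond ±3·maxnoise are excluded, as are runs
staying beyond ±maxnoise for > 0.2 s, padded by 0.1 s on each side; the
mask applies to 470, 405 and velocity alike, and > 5% masked bins rejects
the recording. Note the acknowledged circularity: maxnoise is computed from
a residual that still contains the artifacts. Arithmetically this means
sub-smoothing-window (< ~0.1 s) deflections can never trip the rules — a
w-bin spike keeps ≥ (1 − w/10) of its height in the residual, so it inflates
maxnoise by at least half its own amplitude — and only sustained
deflections, which the smoothed trace follows, are catchable. The
generator's artifacts are therefore ~0.3-s plateaus with raised-cosine
ramps longer than the smoothing window (realistic for brain-motion
artifacts); spiky sub-0.1-s events are invisible to this procedure by
construction.

## Locomotion analysis

Bout segmentation is seed-and-extend hysteresis: movement seeds where
|v| > 0.024 m/s and extends through contiguous |v| > 0.010 m/s; isolated
one-bin movements (no other movement within two bins) are dropped; rests
< 0.5 s are merged; bouts are retained if > 0.5 s with mean velocity
> 0.2 m/s; ≥ 100 s total locomotion is required; all bins within 5 s after
any stimulus are removed from the analysis mask (this applies to every
locomotion statistic, including event detection). Acceleration is the first
difference of the 6-bin-smoothed velocity × 100 Hz, final bin padded by
repetition.

Cross-correlations are Pearson correlations per lag over the included pairs
at that lag (means and s.d.s computed on those pairs), lags −1…+1 s in
0.01-s steps (201 lags; the "±100 bins" convention). This keeps |r| ≤ 1
exactly under masking and makes r_xy(ℓ) = r_yx(−ℓ) an identity. A recording
whose 405-vs-acceleration control cross-correlation peaks above 0.1 is
excluded from locomotion analysis.

Movement events are zero-crossing-delimited acceleration intervals with
duration ≥ 0.05 s and peak beyond ±2 m/s², rejected if any other
beyond-threshold acceleration falls within 0.25 s of the interval. Event
*times* are interval starts (the triggered-average trigger point); the
extremum time is also kept. Onsets require reaching 0.4 m/s within 0.75 s
of moving with an initial acceleration peak ≥ 1 m/s² and no velocity below
−0.05 m/s; offsets are the time-reversed conditions.

Quintile analysis ranks events by |peak acceleration| (ties by time) into
five equal-count groups, remainder to the lowest groups (23 events →
5,5,5,4,4). The per-quintile amplitude is max of the triggered-average ΔF/F
in (0, 1] s minus its value at t = 0. `percent_change` is the Q5/Q1 ratio
× 100 (the convention in which a 2.14-fold increase prints as 214%);
`ratio` is the plain fold change (identical events → 1).

Velocity tuning bins ΔF/F by velocity with edges −0.05:0.1:0.75 then ∞;
empty bins are NaN.

## Stimulus responses

Rewards are included only if a lick falls in (delivery, delivery + 1 s];
rest rewards additionally require no |a| > 2.5 m/s² within ±0.75 s and no
|a| > 1.5 m/s² within +0.4 s. The response integral is the Riemann sum
(bin × 0.01 s) over the 50 bins of (+0.05, +0.55] minus the 50 bins ending
one bin before delivery ((−0.5, 0), delivery bin excluded from both
windows): equal counts make a constant trace integrate to exactly zero, and
the operator is linear and offset-invariant. A min–max variant rescales
each ±1-s triggered trace to [0, 1] before integrating. Events without a
full window are dropped, never zero-padded. The deceleration split ranks
stimuli by the acceleration integral over the following 0.75 s and halves
them, the extra event (odd counts) going to the smaller-deceleration half.

## Functional signature and classification

The cohort matrix of ΔF/F–acceleration cross-correlations (recordings ×
201 lags) is decomposed by **uncentered** PCA — eigenvectors of XᵀX with no
mean subtraction — so cross-correlation values keep their relationship to 0
and group sizes do not bias the components. Variance explained is likewise
uncentered (Σs²ᵢ / ΣX²). Sign convention: each loading is flipped so its
largest-magnitude element is positive; scores and hence angles inherit
this, so tests assert quadrant *structure* (deceleration-locked profiles in
the PC1-negative half-plane, acceleration-locked in the positive half),
never absolute angles. Held-out recordings (e.g. SNc somas, DAT) are
projected with the fitted loadings unchanged.

The angle is atan2 of the s.d.-weighted (PC1, PC2) scores, mapped to
[0°, 360°) with 0° between quadrants I and IV and angles increasing
counterclockwise; both-zero scores yield NaN. Group comparisons linearize
angles by opening the circle at 45° (the region where fewest recordings
fall), then use two-sided rank-sum tests with a Bonferroni factor (default:
the number of pairs).

k-means (k = 3, k-means++ with 50 restarts, recorded seed) runs on z-scored
reward, air-puff, PC1 and PC2 features; clusters are matched to subtypes by
the maximum-total-overlap bijection (Hungarian assignment, which reduces to
greatest-overlap matching and resolves ties deterministically); accuracy is
the percentage of recordings in their subtype's matched cluster. Chance
for three balanced classes is 33%.

Pairwise distance–similarity compares the circular angle difference
([0°, 180°]) of recording pairs against the Euclidean distance of their
(x, y, z) mm coordinates, grouping within-subtype, cross-subtype
("mismatched") and DAT–DAT pairs. The DAT depth model predicts the mean
cross-correlation at each depth bin as w·Anxa1 + (1−w)·Calb1 with w ∈
[0, 1]; `fit_mixture_weight` inverts this by clipped least squares.

Soma–axon pairs correlate the two 470 ΔF/F traces over ±1 s; the artifact
control is the average of the two mixed-wavelength cross-correlations
(soma-470 × axon-405 and soma-405 × axon-470); a control peak above 0.12
excludes the pair.

## The synthetic generator

The generator's defaults are the study conditions: 15-minute sessions,
stimuli (rewards and air puffs alternating at random) every 10–30 s, small
(4 µl) and large (16 µl) rewards equiprobable, 90% of rewards consumed
(lick burst starting 0.15–0.7 s after delivery, ~8 Hz for 1.5 s).

**Velocity** alternates rests (2–6 s) and running bouts (6–14 s) built from
Gaussian acceleration pulses (σ = 0.06 s): an onset ramp to 0.35–0.6 m/s,
speed steps every 0.6–1.6 s (60% of steps large enough to exceed the
±2 m/s² event threshold), an offset ramp back to rest, plus smoothed jitter
(s.d. 0.004 m/s) so the hysteresis thresholds are meaningful. These rates
were chosen to reproduce the reported per-recording behavior statistics of
the kind of session analyzed (roughly 100+ qualifying accelerations and
decelerations per 15-min recording); with many fewer events the
per-quintile triggered averages are noise-dominated.

**Transients** are difference-of-exponentials kernels (τ_r = 0.05 s,
τ_d = 0.4 s, GCaMP6f-like, ~1-s width; negative-going responses use a
slower τ_r = 0.1/τ_d = 0.6 s dip kernel). Movement-locked transients follow
qualifying events of the profile's locked direction with probability
`follow_prob`, peaking lag ~ max(0, N(lag_mean, lag_sd)) after the pulse
extremum; amplitude is `base_amp · (1 + k·u)` where u is the event's
magnitude quantile and k = (g−1)/(0.9 − 0.1g) makes the *expected* Q5/Q1
ratio equal the programmed `amp_scaling` g (quintile expectations of a
uniform rank are 0.1 and 0.9). Background transients occur at 0.3/s
(lognormal amplitudes, median 12% ΔF/F), consistent with the observed
dominance of non-movement-locked transients in such recordings, and keep
the QC transient rate above 0.2/s. One **anchor transient** of exactly
100% ΔF/F is placed mid-way through the longest rest so the session's
largest transient — and hence the 0–100 comparison scale — is well defined;
without it the normalization target would be a random draw and programmed
response integrals (which are specified in normalized units) could not be
meaningfully calibrated.

**Stimulus responses** are calibrated analytically: the expected response
integral of a unit-amplitude kernel under the lag distribution
(N(0.3 s, 0.05 s)) is computed by Gauss quadrature, and amplitudes are set
to target ÷ gain, with mean-one lognormal jitter. Small/large reward
amplitudes target R ∓ d/2 and R ± d/2 so the mean response is R and the
large-minus-small difference is the programmed `size_sensitivity` d.

**Fluorescence**: `F = B(t) · F₀ · (1 + 0.15 · x/100)` where x is the
latent percent signal (transients + shared artifacts + Gaussian noise,
s.d. 1% per channel) and B(t) is a double-exponential bleach (amplitudes
0.3/0.7, time constants 90/2500 s — roughly two-fold over 15 min; the 405
channel bleaches with slightly different constants). The 0.15 factor makes
the background-light share exactly the 0.85 the preprocessing subtracts, so
the pipeline's ΔF/F recovers the latent in percent units; the 405 latent
contains artifacts and noise but no calcium signal. Artifacts are ~0.3-s
plateaus at 10–14× the noise s.d., injected into both channels with
independent gains near 1.

**Profiles** (defaults): deceleration-locked with lag 0.42 s / follow 0.624
/ Q5-Q1 gain 2.14 / reward 7.9 / air puff 15.8 / size contrast 0.9
(Vglut2-like); deceleration-locked 0.17 s / 0.623 / 2.43 / 12.4 / 5.3 / 3.9
(Calb1-like); acceleration-locked 0.30 s / 0.575 / 2.06 / −0.5 / −3.7 / 0
(Anxa1-like; the lag and all amplitude-variance parameters are free choices
documented here, since only the other subtypes' lags are constrained).
Cohort coordinates are Gaussian clouds (s.d. 0.3 mm) around subtype-biased
striatal centers (Anxa1 dorsal, Calb1 medial/ventral, Vglut2 posterior).
Per-session seeds derive deterministically from a base seed via
`numpy.random.SeedSequence`; one named generator per session, no global
state.

### What the generator does and does not emulate

It reproduces the *statistical structure* the analysis assumes: event
locking, lags, amplitude scaling, response integrals, bleach, shared
artifacts, consumption-gated licking, and the anatomical biases needed for
the distance analysis. It does not model biophysical calcium dynamics,
spiking, optics, sensor nonlinearity (real GCaMP decay does not scale
linearly with amplitude — the reason the min–max-scaled analysis variant
exists), correlated noise, slow behavioral state changes, or
within-recording functional heterogeneity. Passing recovery tests therefore
demonstrates that the pipeline measures what it claims on data satisfying
its own assumptions — not that those assumptions hold for any particular
real recording.

## Recovery estimators

`photoline.recovery` defines how generative parameters are measured back
from pipeline outputs:

- **Timing lag**: extremum of the acceleration average triggered on
  detected transient peaks (within the locomotion mask), in [−1, 0] s,
  after 0.05-s smoothing, sign per the locked direction. This directly
  measures peak-to-extremum timing and is far less biased than the
  cross-correlation trough, which the asymmetric kernel drags late.
- **Quintile gain**: the Q5/Q1 ratio of cohort-mean per-quintile
  amplitudes.
- **Follow probability**: the raw event-follow metric (fraction of events
  whose 0.75-s post-event ΔF/F integral, after subtracting the t = 0 value,
  is positive) has a ~0.5 floor for never-followed events. The estimator
  inverts f = p + (1−p)q using the **opposite-direction events as the
  paired null** for q: they share the events' temporal relationship to the
  transient stream, whereas random control bins sit systematically closer
  to upcoming transients and overestimate q. An optional recent-transient
  pre-filter is available but not used by default.

## Problem sizes and tolerances

The validation suite and the acceptance script use cohorts of 10 recordings
per subtype at 15 minutes each — the scale at which the recovery bands
(lags ±0.05 s; robust response integrals 10% relative, 0.5 absolute for the
near-zero reward target; quintile gain 15%; follow probability ±0.07; SNR
20%) hold with margin under the default noise. Unit tests use 1–5-minute
traces. Numerical tie-breaks and degenerate-input behavior (zero-noise
floors, empty event sets, fallback normalization, boundary-extremum flags)
are documented at the function level and exercised by tests.

## Known limitations

- The uncentered-PCA sign convention fixes angles only up to the loading
  flip; absolute angle values are convention-dependent and only their
  *relative* structure is asserted.
- Percentile baseline-tracking attenuates response integrals by ~5–7% at
  realistic transient densities and degrades within one 20-s window of the
  trace ends (see ΔF/F section).
- The artifact-exclusion procedure is blind to sub-0.1-s artifacts by
  construction (see QC section).
- With no detectable transient, the 0–100 comparison scale is undefined and
  falls back to the trace maximum (flagged); such recordings fail QC anyway
  under the transient-rate criterion.
- Light stimuli are carried through the data model but never analyzed, and
  the treadmill is one-dimensional: no gait, posture or video-based
  behavior.
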