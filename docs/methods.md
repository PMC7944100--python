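# Methods

`resteeg` implements a resting-state EEG biomarker analysis for working
memory in older adults: from 14-channel wearable-headset recordings
(128 Hz; AF3, F7, F3, FC5, T7, P7, O1, O2, P8, T8, FC6, F4, F8, AF4 in
the 10–20 system) and a delayed-match-to-sample (DMS) behavioral
session to band-power tables, magnitude-squared coherence networks, and
electrode-/edge-wise Pearson correlation maps against retrieval
accuracy and speed. Because no human recordings are distributed with
the package, a synthetic-cohort generator with exactly known ground
truth stands in for the study data; every downstream stage is validated
against quantities that generator plants.

## Analysis pipeline

**Preprocessing.** Per recording: (1) bad-channel rejection — a channel
is *flat* if any contiguous 5-s stretch has peak-to-peak below 0.5 μV,
and *peaky* if its whole-recording peak-to-peak has a robust z-score
above 5 across channels (median/MAD, with the MAD floored at 10% of the
median so that genuine regional amplitude differences — e.g. elevated
occipital alpha — on an otherwise homogeneous montage are not flagged;
both thresholds configurable, neither is a published value); rejected
channels are removed, never interpolated. (2) Zero-phase 4th-order
Butterworth band-pass 0.5–46 Hz. (3) Common-average re-reference.
(4) Artifact subspace reconstruction (ASR), simplified: non-overlapping
0.5-s windows are ranked by total RMS and the cleanest 50% form the
calibration set; its covariance yields an orthonormal component basis
and per-component statistics of calibration window variances. Each
50%-overlapping 0.5-s analysis window is projected onto the basis; any
component whose variance exceeds `mean + 20·SD` of its calibration
window variances is rescaled down to the calibration-mean variance and
back-projected, with Hann-weighted overlap-add so reconstruction never
introduces boundary discontinuities. The 20-SD statistic is the
detection rule; reconstruction targets the calibration level because
clamping to the 20-SD boundary itself would leave several times the
normal variance in place (blink windows would retain ~20% of their
excess). This is a deliberate simplification of published ASR (no
calibration mixing-matrix machinery); it preserves the
variance-classification behaviour. (5) A minimum-duration guard
(default 60 s) aborts, naming subject and condition, if less remains.

Order of operations: bad channels are removed *before* re-referencing
so they cannot contaminate the common average; ASR runs last on the
referenced, filtered signal.

**Spectral estimation.** Welch's method with 4-s Hann-tapered epochs
and 2-s overlap: at 128 Hz that is 512-sample segments on an exactly
0.25 Hz grid. One-sided densities are taper-compensated so the
integral over all frequencies equals the mean per-segment variance.
Band powers are bin sums over half-open bands (delta 1–4, theta 4–8,
alpha 8–13, beta 13–28, gamma 28–46 Hz) — shared edges are counted
once, in the upper band — reported as integrated power (μV²), mean
density (μV²/Hz), and relative power (share of total 1–46 Hz power).
Magnitude-squared coherence `|G_xy|²/(G_xx·G_yy)` uses the identical
segmentation for auto- and cross-spectra, which keeps the estimate in
[0, 1] without clipping (Cauchy–Schwarz) and makes the network matrix
exactly symmetric with a unit diagonal. For independent signals the
estimator's bias is ≈1/K (K = 29 segments for 60 s); the Hann overlap
inflates this only mildly (measured ≈0.036 vs 1/29 ≈ 0.034).

**Behavioral task.** The DMS session is 2 blocks × 8 trials × 12 test
items (6 targets — 3 presentations of each of the 2 encoded targets —
and 6 unique distractors), 3-s encoding presentation plus a 2-s
consolidation gap (honouring both the "5 s to memorize" and "presented
for 3 s" descriptions), 1-s test-item presentations, uniform 1.6–1.8 s
jitters, response hand swapped between blocks. Trial duration is
emergent (≈40 s), not enforced. The simulated responder is Bernoulli
per item for correctness and lognormal for RT (mean/SD parameterised on
the ms scale, non-target mean shifted +25 ms, truncated at the 1-s
response window + 500 ms grace). Non-responses count as incorrect and
contribute no RT, keeping the accuracy denominator equal to presented
items. Kruskal–Wallis (midrank ties correction, chi-square reference)
is the group test; the all-identical degenerate case returns H = 0,
p = 1.

**Correlation mapping.** Pearson r per (band, channel) cell — 70 cells
— or per (band, channel-pair) edge — 455 edges — against a behavioral
measure, subjects matched by id with pairwise deletion. Two-tailed p
from `t = |r|·sqrt(n−2)/sqrt(1−r²)` at n−2 df. Significance is
uncorrected p < α (default 0.05), matching the exploratory
electrode-wise convention for exploratory biomarker maps; a Benjamini–Hochberg
switch is provided as an extension. Maps default to relative band
power (the scale of the published topographies); absolute density is a
config switch.

## Synthetic cohort

**Signal model.** Each recording is a sum over bands of band-limited
Gaussian processes, synthesized in the frequency domain: complex
Gaussian rFFT coefficients, flat at the target one-sided density inside
the band, zero outside. This is band-limited noise with an ideal
filter: spectra are exactly flat in-band, there is no inter-band
leakage at the synthesis resolution, and planted coherence has a clean
closed form. Per subject, band, and channel the density is scaled by a
unit-mean lognormal factor `exp(σz − σ²/2)` with independent standard
normal latents z and σ = `subject_sd_log` = 0.4 — a free parameter (the
study does not report between-subject band-power dispersion; its
reported occipital-alpha group SD of ±4.32 μV²/Hz would imply an
implausibly small ~11% CV, and is not matched; only group means are
targeted). Eyes-closed multiplies occipital (O1, O2) alpha density by
`ec_alpha_boost` = 38.80/35.65 ≈ 1.088, the ratio of the published
eyes-closed to eyes-open occipital alpha levels; baseline densities are
delta 12, theta 8, alpha 10 (occipital 35.65), beta 4, gamma 2 μV²/Hz —
generic resting magnitudes apart from the published occipital values.

**What "target density" means.** Configured densities are defined as
what the analysis pipeline measures on clean data, i.e. Welch band
averages of the average-referenced signal. Two linear operators
separate the synthesis scale from that measurement scale, and both are
inverted at generation: (a) the common-average reference mixes
channels — for independent channels it maps densities through
`(1−1/C)²` on the diagonal and `1/C²` off it, a 14×14 solve per band;
(b) the 4-s Hann spectral window smears band-edge bins into
neighbouring bands — a 5×5 band-coupling matrix computed from the exact
taper kernel, inverted per channel (without it, measured delta is
biased −4.7% and occipital alpha −3.3%). The two operators commute
(one is diagonal in channels, the other in frequency). The reference
inversion is exact for independent channels and approximate when
coherence edges are planted. The analysis band-pass roll-off at the
top of the gamma band (−13% on the 28–46 Hz average) is deliberately
*not* compensated: it is the analysis chain's own behaviour, shared by
any pipeline that low-passes at 46 Hz.

**Planted coherence.** An edge (i, j, band) shares one band-limited
unit source s between the two channels: `x = sqrt(1−w²)·u + w·s`,
which leaves each channel's density unchanged and yields
magnitude-squared coherence exactly w⁴, so `w = coherence^(1/4)`.
Behavior-linked edges draw per-subject coherence
`clip(0.5 + 0.12·z, 0.02, 0.98)` from the subject's edge latent.

**Planted behavioral correlations.** Covariates are planted against
the standardized *linear-scale* true feature (the lognormal density
multiplier standardized by its exact moments, or the edge latent):
`y = Σ ρ_k·x_k + sqrt(1 − Σρ_k²)·ε`, then mapped affinely to the
published scale (RT 673 ± 51 ms; accuracy 91.56 ± 5.02%, clipped to
[0, 100]). Planting on the linear scale rather than on the Gaussian
log-latent makes corr(behavior, true density) equal ρ exactly, which is
the recovery contract the tests check; planting on the latent would
leave a latent→lognormal attenuation of a few percent. Clipping the
accuracy tail at 100 (≈1.7 SD above its mean) costs under 1% of a
planted correlation. Incompatible effect sets (Σρ² ≥ 1 on one measure,
or two effects on the same feature) are configuration errors.

**Artifacts.** Blinks are raised-cosine transients, 0.4 s, 300 μV at
AF3/AF4 decaying exponentially with head-plane distance (length scale
0.6); muscle events are 0.5-s, 40 μV-RMS bursts of 20–46 Hz noise on a
random channel; an optional flat channel zeroes one channel for 6 s.
Default rates — chosen once, as the study reports none: blinks 2/min
with the eyes open and 0/min with the eyes closed (eyes-closed blink
suppression is physiologically near-total, and the eyes-closed
condition is the one every biomarker analysis consumes), muscle 1/min
in both conditions, flat-channel probability 0 (the published cohort
tables imply complete 14-channel data for all 43 subjects). Every
injected event is annotated with onset, duration, and label.

**Reproducibility.** A cohort is a pure function of its configuration:
per-subject latent, signal, artifact, and behavioral streams are spawned
from the master seed with fixed spawn keys, so regeneration is
bit-identical and changing one subject's stream leaves all others
untouched.

## What the synthetic data does and does not show

The generator emulates band-structured resting EEG with a realistic
montage, the eyes-closed occipital alpha elevation, blink/muscle/flat
artifacts, and power- and coherence-linked behavioral covariates at the
published cohort size and effect sizes. It does **not** simulate 1/f
background structure, volume conduction, ERPs, non-stationarity beyond
injected artifacts, or realistic cross-channel covariance; passing
tests therefore demonstrate that the *pipeline* recovers what was
planted under stationary band-noise conditions, not that the published
human effects are reproducible from new data.

## Reference experiments and problem sizes

`resteeg.protocols` holds the package's reference experiments, used by
both the heavier tests and `scripts/acceptance.py`:

- **Planted-correlation recovery** — one effect per run at the
  published Table-level coefficients (beta/P8 and alpha/P8 vs accuracy,
  delta/P7 vs mean RT), 200 replicate 43-subject cohorts of 60-s
  eyes-closed recordings; the mean recovered map cell is compared to
  the planted ρ. Recovery is measured on absolute-density features —
  the matched scale for a planted density effect; relative power mixes
  the other bands' independent latents into the denominator and
  attenuates recovered r by ~11%, which is a property of the feature
  definition, not of the estimator. Residual attenuation on the
  absolute scale (Welch sampling noise, small-sample bias of r on a
  lognormal feature) totals 3–6% of ρ at 60 s.
- **Eyes-closed occipital alpha recovery** — default generator, full
  cleaning chain, group mean alpha density over O1/O2 against the
  38.80 μV²/Hz target. A single 43-subject cohort carries ±4.5%
  sampling noise from the subject lognormal alone; the test averages
  10 replicate cohorts to separate systematic recovery from
  single-cohort noise.
- **Behavioral round trip** — 200 replicate 43-subject cohorts of full
  simulated sessions at the published generative levels (target
  correctness 0.9156, RT mean 673 ms).
- **Null calibration** — effect-free cohorts (30 × 43 subjects, 30-s
  recordings); the uncorrected map's p < 0.05 rate over 2100 pooled
  cells is checked against 0.05 within a binomial 3σ band.

## Numerical choices and degenerate inputs

- Epoch windows are half-open `[t0, t0+T)`; samples 0-based; time in
  seconds from recording start; everything in μV at ingest (EDF
  physical dimensions honoured, unknown units rejected).
- Coherence needs ≥2 Welch segments (one segment is identically 1);
  zero auto-spectrum bins yield coherence 0 with a warning.
- Pearson machinery refuses n < 3 and zero-variance inputs; |r| = 1
  returns the p → 0 limit.
- ASR's overlap-add taper has a 1e-8 floor so edge samples (where the
  Hann weight vanishes) normalize exactly; the artifact-free chain is
  an identity to ~1e-6 relative.
- The fixture format is one `.npy` float64 matrix plus a JSON sidecar;
  round trips are bit-exact.
- Default resting duration is 60 s (the protocol's stated session
  length); a 90-s variant is available through configuration.

## Known limitations

- The simplified ASR has no mixing-matrix reconstruction; heavily
  overlapping artifacts spanning many windows are attenuated, not
  modelled out.
- XDF support covers numeric-format, nominal-rate streams (no clock
  resynchronisation, no string streams).
- The gamma band average is attenuated ~13% by the 46 Hz analysis
  low-pass; gamma-level recoveries inherit that.
- Relative-power correlation maps are structurally attenuated for
  single-band planted effects (see above); the published maps'
  relative scale is retained as the default regardless.
- Pearson p-values assume the t transform; under the null with
  non-normal features at n = 43 the calibration error is within the
  binomial band of the null-calibration check.
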