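# Methods

This note documents the models, parameter choices and numerical
conventions of the `fnirspeech` pipeline, and what its synthetic-data
validation does and does not establish.

## Signal model and conversion

Continuous-wave fNIRS measures light intensity at two wavelengths
(695 and 830 nm) per source–detector channel at 10 Hz. The pipeline works
with optical-density change relative to a baseline window,
ΔOD(t) = −log₁₀(I(t)/Ī_baseline), so the arbitrary intensity scale
cancels. The modified Beer–Lambert law relates ΔOD at the two wavelengths
linearly to the two chromophore concentration changes via the extinction
matrix E:

    ΔOD_λ = ε_λ,HbO·ΔHbO + ε_λ,HbR·ΔHbR

The shipped coefficients (in 1/(mM·mm): 695 nm → 0.03174 / 0.18628,
830 nm → 0.09740 / 0.06930 for HbO / HbR) come from the standard
literature compilation for hemoglobin. No differential-pathlength factor
is applied; outputs are therefore concentration × pathlength (mM·mm).
Because every downstream statistic (t, r) is scale-invariant, the choice
of table and units does not affect any reported inference — the 2×2
system only needs to be well conditioned, and tests verify exact
forward/inverse round trips.

ΔtHb is defined as ΔHbO + ΔHbR and recomputed after every stage, so the
identity holds exactly throughout. Statistics use HbO only, the species
with the better task sensitivity; HbR is carried in all files.

## Quality control

Artifact detection uses consecutive non-overlapping 5 s windows on the
HbO series (a trailing remainder of ≥ 2 samples forms its own shorter
window). Samples deviating more than 3 window-SDs from the window mean
are flagged; a channel whose flagged fraction exceeds 5 % is excluded
from all statistics. Non-overlapping windows were chosen over a sliding
stride because they make the contamination fraction well defined (each
sample is judged exactly once); the stride is the window length by
construction. QC runs directly after the Beer–Lambert step, before motion
correction, so the repair cannot hide contamination from the exclusion
rule. A manual exclusion list in the configuration supplements the
automatic rule for channels a human would reject on inspection.
Known limitation: heavy contamination (many large artifacts inside one
window) inflates the window SD and can mask individual spikes; the
fraction rule still catches such channels through their residual flagged
samples, but the per-sample mask is conservative there.

## Motion correction (TDDR)

The implementation follows the published reference algorithm exactly:
split the centered signal at 0.5 Hz (3rd-order Butterworth, forward–
backward, no padding); compute the temporal derivative of the low band;
iterate a Tukey-biweight (c = 4.685) weighted location estimate with
scale 1.4826·MAD until the weight vector changes by < 1e-8 (≤ 50
iterations); reintegrate the reweighted, recentered derivative; restore
the untouched high band and mean. It matches the independent reference
implementation to ~1e-8 on test signals, and collapses a 10 SD step
artifact by ≈ 94 %.

A property of the published method worth knowing: because the biweight
assigns weight ≈ 0.91 to *typical* derivative samples, the low-frequency
band of any signal — artifact or not — is shrunk by roughly 3–7 % in
amplitude. Clean signals are preserved to < 1 % only when their power
lies above the 0.5 Hz split. This is inherent to the algorithm, not to
this implementation; it is one reason the noiseless identifiability check
below runs with the TDDR stage toggled off.

## Filtering

Drift removal projects out the discrete-cosine (DCT-II) basis functions
with frequency k·fs/(2N) below 0.0078 Hz, including the constant. As an
orthogonal projection it is linear and idempotent; tests verify < 10 %
residual RMS at 0.002 Hz and < 5 % passband loss at 0.1 Hz.

The low-pass filter convolves causally with the canonical double-gamma
HRF normalized to unit sum (edge-padded with the first sample, so
constants pass unchanged). Its transfer function attenuates 4 Hz
(cardiac-range) content by > 95 %. The HRF parameters — response peak
6 s, undershoot peak 16 s, both dispersions 1 s, undershoot ratio 1/6,
32 s support — are the standard canonical values, exposed in
configuration; the same kernel, normalized to unit peak, builds the GLM
regressors.

## Condition segmentation

Annotated intervals are half-open [onset, offset) in seconds; sample i
carries the label of the interval containing i/fs (onsets/offsets on the
sample grid map exactly; an epsilon of 1e-9·fs guards float rounding).
Preparation samples outside private-speech intervals are inner speech;
execution is outer speech. Runs shorter than 1 s (configurable) are
merged into the preceding run's label, because a correlation or
regressor over a fragment of a few samples is meaningless. Behavioral
coding segments timed transcripts into utterances at pauses strictly
exceeding 2 s (a gap of exactly 2 s does not split) and reports U, W_PS
(English + Chinese words), U/S (per cumulative private-speech second)
and W/U, with W/U undefined (missing) at U = 0.

## Activation GLM

Per channel, ordinary least squares of HbO on HRF-convolved condition
boxcars plus an intercept. Rest is the unmodeled baseline, so
"condition > rest" is the condition beta against zero — the standard GLM
reading when rest occupies the residual design space; an explicit rest
regressor would be collinear with the intercept over a full partition.
The temporal filters applied to the data are applied identically to the
condition regressors (the standard practice of fitting model and data in
the same filtered space); this also makes the noiseless chain exactly
invertible. The GLM is fitted per block and betas averaged across the two
blocks, mirroring the connectivity block-averaging rule. Group inference:
two-sided one-sample t per channel (df = n−1) for the four contrasts,
pooled-variance two-sample t (df = n₁+n₂−2) for proficiency comparisons,
Benjamini–Hochberg step-up across the 40 channels per contrast with
significance at adjusted p < 0.05. Degenerate zero-variance samples give
t = 0, p = 1 when the mean is zero and are an error otherwise. No
nuisance regressors or AR noise model are included — plain t-tests on
OLS betas are the inferential model throughout.

## Functional connectivity

For each condition, segments of at least 1 s are demeaned individually
and concatenated before the Pearson correlation — segment-level offsets
(e.g. different hemodynamic baselines of separate private-speech bouts)
would otherwise inflate correlations. A minimum of 30 pooled samples is
required. Correlations are clipped to |r| ≤ 1 − 1e-7 before z = artanh r.
Matrices are averaged elementwise over the two blocks (a missing block
passes through, flagged by the block count) and ordered by the eight
region groups. Contrasts are connection-wise paired t-tests, reported as
t, p, −log₁₀(p), and signed uncorrected masks at p < 0.005; BH-adjusted
p over the 780 connections is emitted alongside so either reporting rule
(uncorrected threshold or FDR) can be applied by the reader. Rest
matrices are computed but enter no default contrast.

## Synthetic data generator

Each participant-block is generated as: rest, preparation (with
private-speech intervals drawn to lengths U(10, 30) s — mini profile
U(8, 15) s — separated by ≥ 2 s gaps, snapped to the sample grid),
execution. Channel HbO = Σ_c β[ch,c]·(boxcar_c ∗ HRF) + per-condition
latent-factor mixtures + physiological sinusoids (0.1, 0.3, 1.2 Hz at
0.02, 0.01, 0.015 mM·mm, random phase per channel) + white noise
(SD 0.05 mM·mm per sample). HbR = −HbO/3 + independent noise (SD 0.017)
— a documented coupling adequate for testing the tHb invariant, not a
physiological claim. Both species project forward through the extinction
matrix to ΔOD and intensities I₀·10^(−ΔOD); motion spikes (1–3 samples,
±0.2 OD, 2/min) and baseline shifts (±0.05 OD, 0.2/min) are injected in
OD space — multiplicatively in intensity, where such artifacts arise —
with indices logged in the ground truth. A shared latent factor with
loading a = σ·√(r/(1−r)) on two channels plants a target correlation r.
Everything derives from one integer seed through a SeedSequence, so equal
seeds give bit-identical datasets.

Profiles: the full profile uses the study timing (3 min rest, 10 min
preparation, 5 min execution, two blocks, 44 channels); the mini profile
(1 / 3 / 1.5 min) preserves every structural feature at a fraction of the
cost and is the default problem size for the test suite and the
acceptance script, whose Monte-Carlo studies additionally simulate at the
beta / z-matrix level (the quantities the group statistics consume) to
make 500-replicate calibrations cheap.

What passing these tests shows: the implementation computes the stated
statistics correctly, recovers planted effects at the expected power, and
is calibrated under its own null. What it does not show: robustness to
real-data violations the generator omits — superficial/systemic
physiology shared across channels, optode-coupling drift, non-Gaussian
noise, subject-specific HRF shape, or head-motion kinematics beyond
spike/shift artifacts.

## Numerical conventions and degenerate inputs

- Noiseless identifiability: with noise, latents and artifacts at zero,
  the chain simulate → ΔOD → Beer–Lambert → filters → GLM returns planted
  betas to < 1e-6 relative error. This runs with TDDR off (nonlinear,
  see above) and relies on data and design sharing the same linear
  filters; both toggles are ordinary configuration.
- Constant channels in connectivity yield masked (NaN) rows with a
  warning; montage- or QC-excluded channels carry NaN through all
  statistics and are skipped by FDR.
- The baseline window for ΔOD defaults to the whole recording; analyses
  that need exact recovery use the rest phase.
- Pipeline reruns are cached per participant keyed by a SHA-256 of the
  raw inputs and configuration; unchanged reruns are byte-identical.
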