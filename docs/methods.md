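# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limitations of the `mindprobe` pipeline.

## Study design emulated

Seven participants complete seven ~80-minute self-paced computer
sessions with 35 experience-sampling probes each (inter-probe gaps
uniform on 90–150 s), plus two 5-minute eyes-open rest blocks per
session; 32-channel 10–20 EEG is digitized at 256 Hz. Each probe
collects an open-ended activity description and 7-point Likert ratings
on seven thought dimensions (off-task, freely moving, sticky,
goal-oriented, internal, self-oriented, other-oriented). Rest blocks
end with one retrospective report covering the same dimensions except
task-relatedness.

## Synthetic-data generator

The generator's purpose is planted-truth testing, not cortical realism.
Per channel the signal is a sum of three parts:

* **Aperiodic background.** White noise is spectrally shaped in the
  Fourier domain to a one-sided PSD `10^offset · f^−exponent` (µV²/Hz),
  flattened below 1 Hz. Offset and exponent are drawn once per
  participant (defaults: offset U(0.5, 1.5) log₁₀ µV²/Hz, exponent
  U(0.8, 1.4)) and reused across that participant's sessions. A
  log-log regression of the generated PSD over 4–30 Hz recovers the
  configured exponent to within ±0.02.
* **Base oscillators.** Narrowband-filtered independent noise sources
  (4th-order Butterworth, forward-backward) projected through Gaussian
  scalp topographies: posterior 10 ± 1 Hz (4 µV), frontal 6 ± 1 Hz
  (2 µV), central 20 ± 3 Hz (1.5 µV).
* **Planted effects.** Each `EffectSpec` names a dimension, an
  electrode set, a frequency band in [4, 30] Hz, a gain ≥ 0, a sign,
  and a base source amplitude (default 2 µV). A dedicated narrowband
  source on those electrodes is scaled by `max(0, 1 + gain·sign·latent)`
  inside each pre-probe window (and across a whole rest block, using
  the block's latent). Default directions follow the qualitative
  task-condition findings (e.g., off-task ↑ posterior low alpha,
  goal-oriented ↓ widespread high beta); they are researcher-set test
  fixtures, not effect-size estimates — the true report–EEG coupling in
  humans is unknown.

**Latent thought states** are 7-vectors, standard normal marginally
with a configurable correlation matrix (defaults encode mild, plausible
structure, e.g. off-task–internal r = .4, freely-moving–goal-oriented
r = −.3). Latents are piecewise-constant over each pre-probe window so
a probe's label is exactly valid for its analysis window; the
modulation window defaults to 16 s, the largest analysis window, so
8/12/16-s analyses all see fully modulated data. Ratings are
`round(4 + 1.5·latent + noise)` clipped to 1..7, noise SD 0.5; with the
midpoint discarded this yields roughly 40/20/40 lower/discarded/upper
splits. Gaps are drawn uniformly and the recording is extended past the
nominal duration if needed so exactly `n_probes` probes fit.

What the generator does **not** emulate: artifacts (blinks, muscle,
line noise), volume-conducted source geometry, non-stationary
backgrounds, serial dependence of thought reports. Passing tests
therefore demonstrate the correctness and calibration of the
estimators, not their robustness to artifact-laden human EEG.

## Preprocessing

Band-pass 1–55 Hz (4th-order Butterworth, forward-backward for zero
phase), notch at 60 and 120 Hz (IIR notch, Q = 30), segmentation into
non-overlapping 2-s epochs tiled from t = 0 with 1 s of
reflection-padded context per side, then common average reference.
The interactive artifact steps used with human data (ICA, visual
rejection, channel interpolation) are deliberately absent — synthetic
inputs are artifact-free — so the module is unsuitable on its own for
real recordings. Pre-probe windows keep epochs whose 2-s cores lie
fully inside `[probe − window, probe)`; a probe at t with window 12 s
yields up to 6 epochs, truncated near the recording start.

## Spectral features

Welch PSD per epoch core: 1-s Hamming segments stepped by 0.5 s
(3 segments), density scaling, no detrending, evaluated on the 4–30 Hz
1-Hz grid. The phrase "0.5-second overlapping windows" is ambiguous
between window length and step; 1-s segments with a 0.5-s step are
used because a native 1-Hz grid requires ≥1-s segments. This is the
package's declared spectral dialect.

The aperiodic component is a per-electrode robust line in log₁₀-power
vs log₁₀-frequency: ordinary least squares, then twice excluding
points more than one residual SD **above** the line (candidate peaks)
and refitting. Only the line is needed downstream, so no Gaussian peak
model is fit. Subtraction happens in log space; features are log₁₀
residuals ("periodic power"). Against planted spectra with a
0.5-log-unit peak and session-mean-scale log-noise (SD 0.025,
equivalent to averaging ≈300 Welch segments) the exponent is recovered
within ±0.1 in ≥95% of draws for exponents 0.5–1.5; single-epoch
spectra are far noisier, which is why session-level averages feed the
group statistics.

## Labeling and inclusion rules

Dichotomization: 1–3 → lower, 4 → discarded, 5–7 → upper, applied per
dimension, so one probe can be discarded on one dimension and usable
on another. Sessions lacking trials on either end of a dimension are
excluded from that dimension's group analysis. At rest, every 2-s
epoch of a block inherits the block's retrospective labels; a
dimension is excluded cohort-wide if any participant lacks one end
across all rest sessions. Covariate selection ranks the other
dimensions by |Pearson r| with the target's ratings, computed within
sessions and combined across sessions by Fisher-z averaging (the
aggregation and the use of absolute correlation are package choices;
zero-variance rating vectors get r = 0 with a warning).

## Group statistics

**Cluster-based permutation test.** Units are session-level
(upper, lower) mean-matrix pairs. The paired t-map (df = n−1; cells
with zero-variance, zero-mean differences set to t = 0) is thresholded
at the two-tailed critical t for α = .05 (configurable). Suprathreshold
cells form clusters through electrode neighbors at the same bin and
±1-Hz bins at the same electrode (no diagonal links); electrode
neighborhoods come from 2-D layout distance below 0.30 (mean degree
≈5.5 on the packaged montage). The statistic is the maxsum cluster
mass; the null is the maximum |mass| over within-pair sign flips,
pooled over signs. Monte-Carlo p-values use (r+1)/(n+1) with 1000
flips by default; when 2ⁿ ≤ n_perm all sign patterns are enumerated and
p = r/2ⁿ (minimum 1/2ⁿ). Under the global null the family-wise error
rate sits near the low side of the nominal 5% (the pooled-sign maximum
is mildly conservative). The implementation is cross-checked against
MNE's cluster test in the suite.

**Mixed models.** The end-effect model is
`response ~ end + (1|participant) + (1|participant:session)` on
session × end mean periodic power inside a significant cluster, fit
with statsmodels MixedLM. Estimates and Wald 95% intervals come from
the REML fit; the end-effect p-value is a likelihood-ratio χ²(1) test
between ML fits. Simulating from the generating model, interval
coverage is ≈95%. The covariate model drops the session component
(matching its specification) and adds the top-3 correlated dimensions'
session × end mean ratings; rank-deficient covariates are dropped with
a warning and flagged. Singular or non-converged fits are flagged, not
raised.

**Task-rest similarity** is the Pearson correlation over the 864 cells
between the grand (upper − lower) difference matrices of the two
conditions — difference maps, not per-end means, are compared, since a
difference map is the dimension's signature.

## Decoding

The 1D shallow CNN treats the 32 electrodes as input channels and the
27 frequencies as the convolution axis: conv(7, 25 filters) → ReLU →
conv(5, 20 filters) → ReLU → global average pooling → dropout 0.1 →
dense(2) → softmax, 8,187 trainable parameters, two-class
cross-entropy, Adam. It is implemented in NumPy (im2col convolutions,
analytically verified gradients); a fixed seed fully determines
initialization, batch order, and dropout, so training is reproducible.
"Validation to avoid overfitting" is realized as early stopping on
validation loss with patience 10 and best-weight restoration.

Evaluation follows the two-route protocol. Within-participant:
stratified five-fold CV per eligible participant (≥50 trials per class
at full scale; the eligibility threshold is configurable), 10% of each
training fold held out for validation, z-scoring statistics and SMOTE
balancing computed on the training partition only, metrics on the
untouched test fold, averaged folds → participant → iteration, with 25
iterations summarized as mean (SD). Across-participant: train on all
others (90/10 split, SMOTE), evaluate unadapted, then fine-tune on a
SMOTE-balanced stratified 25% of the held-out participant (patience on
training loss) and evaluate on the remaining 75%, which never enters
any training stage (id-audited). Stratified folds are the default and
probe-grouped folds are available via `group_folds=True`; epoch-level
splitting is the default, which lets epochs of one probe appear on
both sides of a fold — a deliberate, documented mirroring of the
evaluation design rather than a leakage bug, avoidable with the group
flag. Significance: label shuffling within participant, rank p with
the add-one convention against 25 shuffled runs, plus a two-sample
Wilcoxon rank-sum between observed and shuffled value sets (two
independent sets, hence the two-sample variant).

SMOTE synthesizes `x + u·(x_nn − x)`, u ~ U(0,1), x_nn among the k = 5
(capped at m−1) nearest minority neighbors, until class parity.
Metrics use their closed forms; AUC is the tie-aware normalized
rank-sum statistic.

## Problem sizes used in tests and the acceptance script

The estimator-level checks run at their stated sizes (200 null
simulations × 500 permutations for type-I error; 100 planted runs;
200 interval-coverage simulations). The end-to-end decoding checks use
reduced cohorts — 4 participants × 2 sessions × 18 probes (gain 0.5)
with 25-to-35-s gaps for the planted check, 2 × 1 × 15 for the
zero-gain null — with the CNN at learning rate 10⁻² and ≤60 epochs,
settings chosen so the whole suite runs at desk scale; the acceptance
script uses 3 × 2 × 15 with 5 CV iterations and 10 permutation runs.
The per-trial planted effect at gain 0.5 is weak by construction
(single-epoch Welch spectra average only 3 segments), so within-
participant MCC on synthetic cohorts sits near 0.05–0.15 — the
relevant claims are directional (above the shuffled null; transfer
adaptation not worse than none), not magnitude reproduction.

## Known limitations

* Plain EDF export (fixed header date for byte-identical reruns)
  carries no annotation track; probe times live in the reports CSV and
  ground-truth JSON sidecar.
* The robust-line aperiodic fit has a small positive exponent bias
  (~0.03 at exponent 1.5) when a strong peak is present; acceptable
  because only the subtracted line is used.
* Single-CPU NumPy training limits practical cohort sizes; the CNN is
  small (8k parameters) so this is a throughput, not a memory, limit.
* The generator's reporting model (affine quantization of a Gaussian
  latent) produces symmetric rating distributions; skewed or bimodal
  human report patterns are not emulated.
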