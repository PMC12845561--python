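# Methods

## Problem and approach

`cardiofuse` estimates cardiac output (CO, L/min) noninvasively from two
wearable signals: a single-lead ECG sampled at 250 Hz and a finger
photoplethysmogram (PPG) sampled at 75 Hz. The reference standard is
pulmonary-artery-catheter (PAC) continuous thermodilution, which refreshes
CO/CI on a 1-minute computational cycle and streams values every 2 s.

The central modeling idea is *body-size normalization*: instead of
regressing CO directly, a network regresses the cardiac index
CI = CO / BSA (L/min/m²), where BSA = √(height·weight/3600) m² (Mosteller),
and CO is reconstructed *indirectly* as ĈO = ĈI × BSA. Because CI removes
the between-patient body-size component of CO variance, the indirect route
improves absolute-error agreement (MAE/RMSE/bias) over direct CO
regression; correlation-type metrics are less affected. The package
implements both routes plus the full method-comparison panel needed to
compare them.

## Fusion network

Both 60 s waveform windows (15,000 samples at 250 Hz each) pass through
per-modality *temporal tokenizers* of two identical blocks:

    Conv1d(32 filters, k=7, same) → ReLU
    → depthwise Conv1d(k=7) → pointwise Conv1d(1×1, 32) → ReLU
    → squeeze-and-excitation (32 → 4 → 32, sigmoid gates)
    → average pool (5)

so the temporal resolution falls 15,000 → 3,000 → 600 tokens of 32
channels; a kernel of 7 samples spans 28 ms at 250 Hz (QRS-scale features),
and several tokens cover each cardiac cycle. A single-head scaled
dot-product cross-attention uses ECG tokens as queries and PPG tokens as
keys/values (d_k = 32; all four projections, including the output
projection, are bias-free), letting each ECG time point attend to the PPG
features — delays and amplitudes — that encode pulse transit time and
stroke volume. Global average pooling of the ECG tokens, PPG tokens and
attention output gives three 32-vectors, concatenated into a 96-dim fused
feature, followed by Dense(64)-ReLU-Dropout(0.3), Dense(32)-ReLU-
Dropout(0.3) and a single linear output neuron.

The exact sublayer inventory (dual conv per block, biases on convolutions
and SE, bias-free attention, no normalization layers) was frozen by a
constraint search over the discrete design space so that the trainable
parameter count is exactly **33,745** (and in any case below the 50 k
lightweight budget); this count is the one bit-exact architectural
checksum the design is anchored to, and a unique configuration in the
searched space reproduces it. A single-convolution block reading cannot
exceed ≈29 k parameters, which is why each block carries a standard
convolution followed by the depthwise-separable refinement.

The network, its backward pass, and Adam are implemented directly in
numpy (float32, im2col/BLAS matmuls, numba kernels for the memory-bound
depthwise convolution). Correctness of the hand-derived gradients is
checked against central finite differences, and the scaled-dot-product
softmax rows are property-tested as probability vectors.

## Loss and optimization

Training minimizes `L = Huber_δ=1(ŷ − y) + λ·(1 − CCC)` with λ = 0.1. The
Huber term is outlier-robust; the concordance correlation coefficient
term, `CCC = 2σ_xy / (σ_x² + σ_y² + (μ_x − μ_y)² + ε)` with ε = 1e-6 and a
[−1, 1] clip, penalizes systematic bias and scale shrinkage beyond mere
decorrelation. The loss-side CCC uses population (divide-by-n) moments and
is computed per batch; its analytic gradient is tested against finite
differences at 1e-4 relative tolerance.

The reference schedule is Adam at 1e-4, batch 32, up to 1000 epochs, early
stopping after 20 epochs without validation improvement (strict decrease
by >1e-8), learning rate halved after 4 stagnant epochs with a 1e-6 floor,
and restoration of the minimum-validation-loss weights. The scheduler is a
standalone object so its plateau/stopping semantics are unit-tested on
scripted loss sequences (e.g. losses falling for 30 epochs then flat →
first halving at epoch 34, stop at epoch 50).

Targets are kept in raw physical units by default. The estimator also
offers `standardize_targets=True` (z-score with training-set statistics,
inverted at prediction) and the tests feed it globally standardized
windows; both are single global affine maps that preserve relative pulse
amplitudes across segments.

## Synthetic cohort

The study's clinical recordings are not public, so the package ships a
physiology simulator whose ground truth is known exactly:

* **Anthropometrics**: height ~ N(166, 7.5²) cm, weight ~ N(63, 8²) kg
  (truncated), calibrated so cohort medians land near 167 cm / 63 kg and
  BSA near 1.7 m² — typical of an adult cardiac-surgery cohort. A `spread`
  multiplier widens both SDs to create high-BSA-variance cohorts.
* **CI trajectory**: baseline U(1.8, 3.0) plus three slow sinusoids
  (periods 2–10 min, total amplitude 0.45) plus a bounded random walk
  (SD 0.01·√s), clipped to the clinical range 1.3–4.2 L/min/m², on a 1 s
  grid.
* **Waveforms**: ECG beats are sums of Gaussian P/Q/R/S/T bumps placed at
  R-times whose instantaneous rate is HR = 55 + 8·CI bpm (keeping HR in
  the observed 61–75 bpm range over the CI span); each PPG pulse is a
  gamma-shaped unimodal wave delayed by PTT = 280 − 25·CI ms with
  amplitude 20·SV where SV = CO/HR litres per beat; white Gaussian noise
  (default SD 0.02 of the unit R amplitude) is added to both channels.
  The couplings are stated as package defaults, not literature values,
  and are all overridable.
* **PAC stream**: trailing 60 s mean of CI recomputed each minute,
  repeated on a 2 s grid, CO = CI × BSA; the pre-first-cycle region is
  backfilled with the first completed cycle's value so that the stream
  covers the recording from onset.
* **Artifacts**: noise bursts, baseline wander, and flatlines (sensor
  detachment) over configurable spans, for exercising the quality gates.

What the simulator does **not** emulate: arrhythmia, respiratory
modulation, drug interventions, sensor drift, or patient-specific
waveform morphology differences. Passing tests on this cohort therefore
demonstrate that the pipeline and model behave correctly and learn the
encoded physiological couplings; they do not certify clinical accuracy on
real recordings.

An important structural property of the PAC emulation: labels are trailing
60 s means refreshed per minute, so they *lag* the in-window physiology.
On drifting trajectories even a perfect in-window CI reader correlates
only ≈0.86–0.89 with those labels. Recovery of the simulator's couplings
is therefore evaluated against the trajectory's true in-window mean CI —
the ground truth the cohort exists to provide — rather than the lagged
monitor output used for training.

## Preprocessing

The ECG path applies no filtering (fine P/QRS/T structure is the signal);
it is only Fourier-resampled if not already at 250 Hz. The PPG path is
band-passed with a zero-phase (forward–backward) 4th-order Butterworth at
0.5–4 Hz, smoothed with a Savitzky–Golay filter (window 51 samples, cubic),
then Fourier-resampled to 250 Hz. Filtering happens at the native 75 Hz by
default, where the 51-sample window spans ≈0.68 s (`filter_at="250"`
switches the order). PPG amplitude is never rescaled per segment — pulse
amplitude carries stroke-volume information.

Quality is scored by template correlation: each detected beat's QRS window
(±100 ms) or pulse window (±350 ms) is correlated with the segment-mean
template, and the per-segment mean correlation is standardized as a
Z-score over all segments of the same modality in the cohort; segments
with |z| > 2 are excluded. Two degenerate-population rules apply: a
zero-variance population excludes nothing, and inside the pipeline the
gate is inert when the population's raw-score SD is ≤ 0.01 — template
scores that agree to a few parts in a thousand should not manufacture
outliers (on noise-free cohorts plain z-scoring would still flag ~5–15% of
windows, since z is scale-free). Beat detection is a simple
prominence-plus-refractory peak picker, sufficient for the synthetic
waveforms; proprietary device detectors are out of scope.

## Segmentation and labeling

Synchronized 250 Hz records are cut into 60 s windows (15,000 samples)
with a 30 s stride. Two labeling policies exist: `window_mean` (default) —
the mean of all streamed PAC values inside the window — and
`nearest_minute` — the value at the 1-min reference timestamp nearest the
window midpoint t_mid = t_start + 30 s. Either way a window whose nearest
reference is more than 30 s from t_mid stays unlabeled and is excluded.
Exclusion reasons are coded: missing label, NaN samples, peak-to-peak
amplitude below 1% of the patient-median window amplitude (sensor
detachment), or quality |z| > 2. Splits are randomized at the patient
level (largest-remainder rounding of ratio·n, so 27 patients at
16:5:6/27 give exactly those counts) and leakage is asserted on every
split.

## Statistics

Agreement metrics: Pearson r (PCC), Lin's concordance (CCC, population
moments), R² (1 − SSE/SST, may be negative), MAE, RMSE, and percentage
error PE = 100·SD(ŷ−y)/mean(y) with the PE < 30% clinical acceptability
convention. Bland–Altman bias and 95% limits of agreement use the sample
(n−1) SD; the bias CI uses the exact t quantile and the LoA CIs the
standard variance formula Var(LoA) ≈ (1/n + 1.96²/(2(n−1)))·SD² with a
normal quantile by default (`exact_t=True` available). PCC intervals use
Fisher's z transform; CCC/R²/MAE/RMSE/PE intervals use segment-level
percentile bootstrap (2000 draws by default) — a within-patient clustering
caveat is attached to every report, since overlapping windows from one
patient are resampled independently. Model comparison on a shared
reference uses: a paired permutation test for PCC (per-segment A/B label
swaps, 5000 permutations, add-one smoothing of the two-sided |ΔPCC|
tail), bootstrap difference tests for CCC and R² (3000 paired resamples,
doubled smoothed tail proportion), and Shapiro–Wilk-gated paired t /
Wilcoxon signed-rank tests on per-segment absolute, squared, or signed
errors for MAE, RMSE and bias.

Convention split, deliberate and tested: loss-side CCC uses population
moments with the ε guard; evaluation-side CCC uses population moments
without ε; Bland–Altman and PE use sample SDs.

## Problem sizes in the test suite

The shipped experiments are scaled to single-CPU desk runs, as the
package's own default study sizes: cohorts of 6–20 patients at 10 min per
recording, every second or third overlapping window, batch 16, learning
rate 1e-3 with standardized targets, and 3–25 epochs. Under these
conditions the CI model reaches held-out PCC ≈ 0.9 against ground-truth
CI on a 20-patient cohort, and the indirect CO route beats direct CO
regression on MAE in the majority of seeded replicates on
high-BSA-variance cohorts (the error-metric advantage is the qualitative
finding; correlation metrics are not expected to separate). The full
published schedule (batch 32, lr 1e-4, 1000 epochs, patience 20) is the
estimator default and is exercised on scripted sequences and short smoke
runs.

## Numerical choices and edge cases

* float32 forward/backward; attention logits are clamped at −60 before
  exponentiation (subnormal-float stalls) and SE pre-sigmoid activations
  at ±30.
* Population z-scores (divide-by-n) in the quality gate, matching its
  worked exclusion example; zero/near-zero variance populations exclude
  nothing.
* CCC clipping to [−1, 1] is treated as a flat region of the loss
  (zero gradient) when active.
* Batches of size 1 are skipped during training (batch CCC undefined).
* Bootstrap resamples on which a metric is undefined (zero-variance
  reference draws) are redrawn, with a hard cap to surface pathological
  inputs.
* Ties in nearest-minute labeling resolve to the earlier timestamp
  (argmin convention); windows are half-open [t_start, t_start + 60).

## Known limitations

* The simulator's CI→waveform couplings are linear and noise is white;
  real sensors drift, saturate and move.
* Quality scoring assumes quasi-periodic beats; it is not a general
  signal-quality index.
* The PAC emulator reproduces the 1-min/2-s cadence and trailing-mean
  behavior but not thermodilution measurement noise.
* Patient-level bootstrap is provided only as an option; the default
  segment-level intervals understate uncertainty under clustering.
* EDF/WFDB export is not included; waveform I/O is columnar CSV.
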