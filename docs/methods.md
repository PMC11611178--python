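# Methods

`lumenflow` is a fully automated pipeline that tracks the diameter of a
carotid artery over time from single-scanline (A-mode) ultrasound. This
note describes the model, the synthetic phantom used to validate it, the
numerical choices, and the known limitations.

## Problem setting

A fixed transducer fires short ultrasound pulses along one line through
the neck and records the pulse-echo radio-frequency (RF) signal. Stacked
over time, these A-mode frames form an M-mode (depth × time) record. The
artery appears as two bright wall echoes around a dark (hypoechoic) lumen
whose separation — the diameter — pulsates with the cardiac cycle.
Recovering the diameter waveform per frame gives access to pulse-wave
velocity and arterial-stiffness surrogates.

The pipeline is deliberately two-staged and per-frame (stateless), so it
can run in a streaming setting:

1. **ROI detection** — locate the lumen center along depth.
2. **Diameter regression** — estimate the diameter from a fixed window
   around that center.
3. **Post-smoothing** — remove the frame-to-frame estimation noise.

## Acquisition constants

| Constant | Default | Rationale |
|---|---|---|
| depth samples / frame | 1020 | covers ~25 mm of tissue at the RF sampling rate |
| frame rate | 500 Hz | resolves the systolic upstroke |
| RF sampling | 31.25 MHz | typical front-end rate |
| carrier | 7.8 MHz | vascular imaging band |
| depth scale | 24.65 µm/sample | speed of sound ÷ (2 × RF rate); pulse-echo travel is two-way |

`AcquisitionSpec` validates that the depth scale is consistent with the
speed of sound and the sampling rate (`c / (2 f_s)`), so unit conversions
downstream (`samples_to_mm`) cannot silently drift from the physics.

## Preprocessing

Each frame is reduced to its envelope — the magnitude of the analytic
signal (`scipy.signal.hilbert` along depth) — then normalized to a peak
of 1 per frame. Envelope extraction removes the carrier oscillation;
per-frame normalization removes gain differences between recordings and
slow amplitude drift. An optional block-maximum depth decimation is
provided for coarser inputs; the default pipeline runs at full depth
resolution.

## Stage 1: ROI detector

**Labels.** Instead of regressing wall positions directly, each frame
gets a *response vector* over depth: with lumen center `P_C` and walls
`P_A < P_P`, define cut-offs at the midpoints `(P_C + P_A)/2` and
`(P_C + P_P)/2`; between the cut-offs the label is the downward-opening
quadratic `R_i = 1 − (i − P_C)² / (P_C − P_cutoff)²` (side-specific
denominator) and 0 outside. The bump is 1 at the center, 0.75 at the
quarter points, 0 at the cut-offs. This gives a smooth, translation-
equivariant regression target whose argmax is the quantity of interest.

**Network.** Two 1-D convolutions: 3 channels with a 401-tap kernel
(spanning the widest plausible lumen), ReLU, then a 1-tap channel
combiner — 1210 parameters in total — followed by a *parameterless*
31-sample zero-padded average pooling. The MSE loss is applied to the
pre-pooling map; pooling only smooths the inference-time argmax.
The lumen-center estimate is the argmax of the pooled map, and a fixed
401-sample window around it (shifted inward at frame edges) is passed to
stage 2.

**Training.** Adam (lr 1e-3, decoupled weight decay 1e-4), batch 64,
10 epochs. Because subjects' lumen depths occupy a narrow band, every
epoch re-samples a depth-translation augmentation (±150 samples, clipped
so the walls stay in frame), which forces the detector to respond to echo
structure rather than absolute depth.

Two initialization details matter. The channel combiner is initialized
*positive*: the regression target is nonnegative, and with mixed-sign
combiner weights the first layer's gradients partially cancel, leaving
the optimizer near the all-zero-output saddle. The wide first-layer
convolution is evaluated in the frequency domain (FFT correlation,
forward and backward); this is bit-level equivalent to the direct
zero-padded convolution up to float rounding (covered by tests) and
roughly 30× faster on CPU for 401-tap kernels.

## Stage 2: diameter tracker

**Network.** Five same-length, zero-padded 1-D convolutions (kernel 9)
with batch normalization and ReLU, channels 1→8→16→32→16→8. There is *no
pooling*: the diameter is encoded in the relative position of two echo
peaks, which pooling would blur. A flatten and three fully connected
layers (3208→300→64→1) with dropout 0.2 follow; the final sigmoid output
is scaled by the window width (401), so the estimate is bounded by the
window. The tracker has 993,861 trainable parameters; together with the
ROI detector the pipeline totals 995,071 (~1 M).

**Training.** Huber loss (δ = 1 sample) — robust to the heavy-tailed
errors the envelope produces when the pulse grazes a wall — Adam as
above, 20 epochs, and a step learning-rate schedule (×1 for the first
60 % of updates, ×0.3 until 85 %, ×0.09 after). Training windows are
centered on the *true* lumen center plus uniform jitter of ±25 samples.
The jitter half-range is a robustness parameter: it must cover the tail
of stage 1's localization-error distribution, not its mean. Held-out
subjects whose lumen depth sits at the edge of the training distribution
see ROI errors of 2–3× the across-subject MAE, and a tracker trained
with ±10 jitter degrades sharply on exactly those frames (error
correlation ≈ 0.8 between the stages); widening to ±25 removed both the
correlation-loss and the temporal-lag artifact on such subjects with a
negligible cost on easy subjects. The regression head is zero-initialized
so training starts from the window midpoint rather than a random,
possibly sigmoid-saturated estimate.

## Post-smoothing

The raw per-frame trace carries a small high-frequency noise component
(frames are estimated independently). A Savitzky–Golay filter of order 5
over 31 frames (62 ms at 500 Hz) removes it while reproducing any local
polynomial of degree ≤ 5 exactly — preserving waveform features such as
the systolic foot that a plain moving average (also provided) rounds off.

## Synthetic phantom

No clinical recordings ship with the package; a parametric phantom
provides unlimited labeled data with *exact* ground truth.

- **Diameter waveform**: mean diameter (7.5 mm) + cardiac pulsation
  (raised-cosine upstroke, exponential decay; 0.5 mm amplitude) +
  respiratory modulation (0.2 mm at 7.5 cycles/min) + optional linear
  trend; the lumen center drifts slowly via a random walk.
- **Rendering**: wall reflections are impulses (linearly split between
  the two neighboring depth samples for sub-sample accuracy) convolved
  with a Gabor pulse (Gaussian σ = 4 samples, carrier at the RF carrier
  frequency); tissue speckle is a fixed random scatterer train per
  subject; the lumen interior carries weak scatterers (hypoechoic, not
  silent); bright static "artifact" bands outside the lumen imitate
  other tissue interfaces; white noise on top.
- **Cohorts**: subject parameters (lumen depth, heart rate, artifact
  band positions…) are drawn per subject from a master seed, so a cohort
  is a pure function of `(n_subjects, frames, master_seed)`.

The phantom emulates the *geometry and echo structure* that the pipeline
relies on. It does **not** model beam physics (diffraction, focusing),
attenuation with depth, frequency-dependent scattering, motion blur, or
out-of-plane motion — conclusions about absolute clinical accuracy
cannot be drawn from it. Its role is to validate the pipeline's
mechanics: localization, regression, drift-freedom, and the training
harness.

## Evaluation protocol

Leave-one-subject-out (LOSO): for each subject, both networks are
retrained from scratch on the remaining subjects, the held-out recording
is predicted frame by frame, smoothed, and scored against the exact
phantom truth. The metric suite reports Pearson r, the coefficient of
determination R² (1 − SS_res/SS_tot — *not* r²), Lin's concordance
correlation, MAE/MSE/RMSE, median/mean absolute deviation, a t-statistic
for the correlation, and the skewness/excess kurtosis of the differences.
A cross-correlation peak-lag check verifies temporal alignment (a
drift-free tracker peaks at lag 0). Per-fold training seeds are derived
as `(seed × 1009 + fold) mod 2³¹` and recorded in the provenance dict.

## Numerical engine

The networks run on a small NumPy engine written for this package
(`lumenflow._nn`): im2col/GEMM convolutions (the backward data pass is
itself expressed as one more im2col GEMM against the channel-swapped,
flipped kernel), batch normalization with running statistics, inverted
dropout, Adam with decoupled weight decay, and Huber utilities. All
gradients are hand-derived and verified against float64 central finite
differences in the test suite. Everything trains in float32; a sigmoid
pre-activation clip at ±8 keeps its derivative from underflowing to zero
in float32 (which would otherwise freeze a saturated regression head).
The engine exists because the package targets minimal, easily auditable
dependencies (NumPy/SciPy only for numerics); it is not a general deep
learning framework.

Training cost is bounded per epoch by `frames_per_epoch_*` (ROI 1024,
tracker 2048 by default): each epoch draws a fresh random subset without
replacement, which keeps a full 6-subject LOSO around 15 minutes on one
CPU while every epoch still sees new data.

## Reproducibility

Every stochastic component takes an explicit seed; cohorts, training
runs, and full pipeline reports are bit-reproducible given the same
`(config, seed)`. `run_pipeline` writes the resolved config, per-fold
provenance, and SHA-256 content hashes of every artifact; checkpoints
store all trainable parameters *and* batch-norm running statistics, so a
reloaded model predicts identically.

## Limitations

- The phantom's simplifications listed above.
- Validation thresholds (e.g., mean LOSO Pearson r ≥ 0.87 on the default
  synthetic cohort) characterize this pipeline on this phantom; they are
  not clinical performance claims.
- The ROI argmax is resolution-limited to one depth sample; sub-sample
  center refinement was deliberately left out to keep stage 1 at 1210
  parameters.
- Single scanline only: no B-mode, no DICOM, no device streaming.
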