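# Methods

## Restoration model

All four tasks — denoising, super-resolution, and the two volume
interpolation variants — share one conditional denoising-diffusion core.
Images are mapped from [0, 1] to [−1, 1]; the forward process replaces the
target patch x₀ with Gaussian noise over T steps according to a β schedule;
the network predicts the injected noise ε given the timestep and the raw
conditioning image(s); inference runs the reverse chain from x_T ~ 𝒩(0, I).

**Schedule.** Default: linear β from 1e-4 to 0.02 with T = 1000, for which
ᾱ_T < 0.01 (the chain actually reaches noise). The desk-scale studies use
T = 50; a linear ramp that short leaves ᾱ_T ≈ 0.6, so they use the
squared-cosine schedule instead (ᾱ_T < 1e-6 at T = 50). Both are available
from `build_schedule`.

**Two-head network.** A small U-Net (two encoder levels, bottleneck, two
decoder levels with skip connections) consumes concat(x_t, condition) and
an embedding — sinusoidal timestep encoding, plus the sinusoidal *channel
embedding* of the slice index j for volume work — injected as per-channel
FiLM biases in every block. Each block applies a per-channel spatial RMS
normalisation with a learned gain before the bias and SiLU; this
normalisation roughly tripled the convergence rate of the small nets in the
bundled studies. Head 1 emits ε̂; head 2 emits log φ, clamped to ±10 before
exponentiation so φ > 0 by construction. Both heads are zero-initialised
(ε̂ = 0, φ = 1 at step 0), which keeps the first difficulty-loss steps
bounded; randomly initialised φ occasionally exploded the loss by starting
with φ ≪ 1 under a large residual. Parameters are partitioned into named
groups {encoder, bottleneck, decoder, heads}; fine-tuning trains everything
except the encoder, and the embedding MLP lives in the bottleneck group so
it can adapt during transfer.

The network stack is written directly on numpy: a reverse-mode tape
(`emrestore.nn`) with exactly the operations the U-Net needs, float32
parameters, convolution gradients computed as convolutions with the
spatially flipped kernel, and an Adam optimiser with per-group selection.
At the patch sizes this package targets, single-CPU numpy is entirely
adequate and keeps the dependency surface to the scientific stack.

**Training.** Adam, constant learning rate (5e-5 default, batch 64 — the
published regime; the desk-scale studies use 1e-3 / batch 8 for their tiny
nets), random timestep per sample, augmentations flip / 90° rotation
(square patches only) / Gaussian blur σ ∈ [0.2, 1.0] at p = 0.3.
Checkpoint selection: best validation loss, 20-epoch patience by default.
Fine-tuning: decoder + bottleneck + heads only, lr 1e-5, 200 epochs;
the encoder is frozen bit-for-bit. Anisotropic-only volume training is
capped at 1200 epochs: its training views carry line artifacts, and long
runs overfit to them.

**Sampling.** Reverse transition exactly as in the model equation, with
two numerical choices: the final step (t = 1) adds no noise, so the point
estimate is not perturbed at the last moment; and the x₀ implied by ε̂ is
clamped to [−1, 1] before forming the transition mean (the standard
sampling stabiliser; a prediction already in range is untouched). The
injected-noise variance is Σ_t = (1 − α_t)·I. The difficulty map of the
final step is exposed for inspection alongside the prediction;
quantitative reliability assessment uses the K-sample SD instead.

## Ensembling and uncertainty

Each input patch is restored K times (independent chains, different seeds);
the mean is the prediction and δ, the pointwise SD (ddof = 1; defined
all-zero for K = 1), the uncertainty map. K = 2 by default: one extra draw
stabilises the estimate, while large K averages toward the posterior mean
and re-introduces exactly the smoothness diffusion is used to avoid. A
noise-adaptive K is available through `choose_K`, a monotone step map on a
variance-of-Laplacian noisiness proxy (a reference-free stand-in for a
learned no-reference quality model), defaulting to 2.

Per 256-px patch, each of the K restorations is min-max normalised (flat
patches map to zero rather than dividing by zero), δ is computed, and the
uncertainty value U is the 99th percentile of δ (linear interpolation
between order statistics). The top 1 % of pixels is deliberately excluded:
isolated high-contrast membrane pixels produce large but harmless
deviations. A patch is unreliable when U > τ; the image is flagged when any
patch is, and both the per-patch values and the image maximum are reported.

τ defaults to 0.12 and is a configuration value, not a law: the calibration
path (`calibrate_threshold`) re-derives it for a new dataset from (U,
quality score) pairs by Gaussian-smoothing a 32-bin histogram of the
scores, locating the valley between the two dominant modes (requiring real
bimodality and a valley at most half the smaller mode's height — otherwise
calibration is refused rather than guessed), and averaging the U of the
samples in the valley bin (falling back to the nearest scored samples when
the transition region is empty).

## Registration

Raw/reference pairs are aligned coarse-to-fine. Coarse: ORB keypoints
(1500 per frame), Hamming matching with cross-check and 0.75 ratio test,
RANSAC projective fit at a 3-px inlier threshold, then iterative
least-squares refits on progressively tighter inlier sets (1.5 → 0.5 px) —
ORB localisation is ~1 px, and the refits are what bring corner errors
below half a pixel. A fit is rejected (with the
match count in the error) when fewer than 4 inliers survive or the inlier
fraction falls below 20 %, which is what happens on structureless noise.
Fine: iterative-Lucas-Kanade dense optical flow (radius 8) from the
reference to the coarsely warped frame, estimated on the full frame — the
flow is windowed and local anyway, and whole-frame estimation avoids
patch-seam artifacts — followed by resampling through the field.

All warps use cubic (order-3) interpolation. Bilinear resampling was
measured to cost ~4 % normalised cross-correlation per double warp on
membrane-rich images — more than the registration error itself — so cubic
is a correctness requirement here, not a nicety. Tiling uses 256-px patches
at stride 196 with an edge-snap policy (one final patch flush with each
border, so no pixels are discarded); restitching uses separable tent
weights normalised to sum to one at every pixel, making overlaps convex
combinations and non-overlap regions verbatim copies.

## Synthetic phantoms

The 2D generator renders what EM restoration actually has to preserve:
elliptical organelles with dark membranes and internal cristae-like
lamellae, long curvilinear membranes, and low-frequency cytoplasmic
texture; everything is a pure function of the generating recipe (seed included). The
noise model is Poisson-Gaussian with dwell-scaled variance — shot noise at
`shot_gain·dwell` expected counts plus read noise of variance
`read_sigma²/dwell` — so the pixel SD falls as dwell^(−1/2). Dwell values
are expressed in arbitrary units; the bundled presets use a reference pass
at dwell 18 and raw passes at {16, 4, 1}, i.e. an 18× acquisition speed-up
at the noisiest setting. Drift between paired acquisitions is a global
homography composed with a smooth random displacement field (amplitude-
bounded, single resampling), and the exact transforms are returned for use
as oracles.

The 3D generator produces isotropic (8 nm)³ volumes of blobs with sharp
membrane shells plus tubules drifting laterally along z on sinusoidal
paths. Two properties are deliberate: the axial correlation lengths exceed
the mod-6 retention gap, so the structure genuinely survives anisotropic
downsampling (otherwise slice interpolation is unlearnable by
construction), and the drifting tubules guarantee every volume contains
axial dynamics that per-column cubic interpolation ghosts. The organelle
mask is thresholded at a fixed quantile (0.85) of its random field so the
content fraction is seed-independent.

What the phantoms do *not* emulate: charging, curtaining and milling
artifacts, detector nonlinearity, anisotropic point-spread functions, and
the sheer texture diversity of real tissue. Passing the bundled studies
shows the pipeline is correctly assembled and that the method behaves as
designed on controllable data; it is not evidence about any particular
real dataset.

## Evaluation metrics

PSNR is avoided deliberately: the reference frames carry their own shot
noise. FSIM is computed from phase congruency (monogenic log-Gabor bank, 4
scales, minimum wavelength 6 px, σ/f 0.55, Rayleigh noise floor from the
finest scale) and Scharr gradient magnitude, with the published similarity
constants (T₁ = 0.85, T₂ = 160) on 0-255-scaled inputs. Fourier ring
correlation uses unit-width rings and the 1/7 criterion. The single-image
resolution estimate correlates the spectrum with its phase-normalised,
radially masked counterpart over 50 mask radii; the cutoff is the last
radius with a significant correlation gain (≥ 5 % of the largest
single-step gain) — the curve gains correlation only while the mask still
admits coherent signal, and this plateau-onset rule is robust to the slow
upward drift a flat noise floor produces. Resolution is pixel_size/cutoff,
and the resolution ratio is reference resolution over prediction
resolution (> 1 = sharper than the reference). IoU accepts optional
morphological opening + closing to suppress speck false positives before
scoring; two empty masks score 1.0 by convention.

## Desk-scale study conditions

The learning studies (`emrestore.studies`, also behind
`scripts/acceptance.py` and the acceptance tests) run on one CPU:
32×32-px phantom patches, T = 50 cosine schedule, base-width-16 U-Net,
Adam 1e-3, batch 8, K = 2.

* *Denoising*: 40 phantoms (160 patches, last 20 held out) at dwell 1 —
  the noisy regime where restoration is actually needed — 90 epochs;
  scored as the fraction of held-out patches whose FSIM against the clean
  phantom beats the noisy input's.
* *Isotropic-supervised volumes*: train on z slices of one 64-layer,
  24-px-lateral isotropic volume, reconstruct a mod-6-downsampled second
  volume, score mean MSE of generated layers vs the held-out truth against
  per-column cubic interpolation.
* *Anisotropic-only volumes*: train on the XZ views of the same downsampled
  32-px-lateral volume being reconstructed (the intended practical protocol
  for this variant), with sliding z-crops of the 11-row views as cheap
  augmentation.
* *Uncertainty sweep*: the trained denoiser restores the same phantom
  acquired at dwell {16, 4, 1}; the median patch U must increase as dwell
  falls.

The acceptance tests run each study over 3 seeds with a majority rule; the
stochastic margins at this scale are real, and single-seed flukes in either
direction do occur. Layer indices follow the 1-based construction rules
(upper layer u, lower layer u + R + 1, targets u+1 … u+R) in documentation
and are converted to zero-based indexing at the array boundary. Interleaved
inference output has M + (M−1)·R layers — the printed count in the source
description of this procedure, (M−1)·R + 2, is consistent only for M = 2
and is documented here rather than silently adopted.

## Known limitations

* The numpy network is adequate for patch-scale studies, not for training
  on real 256-px datasets at publication scale; the architecture contract
  (two heads, parameter groups, channel embedding) is what transfers.
* The K = 2 ensemble mean carries half the per-draw posterior variance;
  on nearly-static volumes a 4-support cubic spline can legitimately win
  the MSE comparison, and the studies' majority rule reflects that.
* `choose_K`'s noise proxy is uncalibrated across instruments; it is a
  documented stand-in, and K = 2 is the normative default.
* Uncertainty is epistemic-by-ensemble only; no aleatoric decomposition,
  and no multi-network ensembles.
* At desk scale the uncertainty-vs-noise trend saturates at the noisiest
  setting: median U rises from dwell 16 to dwell 4 but comes out a hair
  *below* the dwell-4 value at dwell 1, because the small model's K = 2
  draws collapse toward the same over-smoothed conditional output instead
  of sampling diverse structure. The gap shrinks steadily with more
  training (it roughly halves when the training length doubles) but does
  not cross within a CPU-scale budget, so the strict-monotonicity check in
  the acceptance suite fails at this scale; the ordering between the
  cleanest and noisiest settings is robust.
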