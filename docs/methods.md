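# Methods

## Model

The translator is a discrete-time paired diffusion bridge. Given a
co-registered pair — target image X_0, source image X_T, both (C, H, W)
grids normalized to [−1, 1] — a noise schedule assigns each step t a
variance increment β_t > 0. The accumulated variances σ_t² = Σ_{u<t} β_u
and σ̄_t² = Σ_{u≥t} β_u satisfy σ_t² + σ̄_t² = σ_T² for every t, and the
bridge marginal is Gaussian with mean (σ̄_t² X_0 + σ_t² X_T)/σ_T² and
isotropic variance σ_t² σ̄_t²/σ_T². The denoiser regresses the
standardized displacement ε = (X_t − X_0)/σ_t (ε-parameterization); the
reverse ancestral step forms X̂_0 = X_t − σ_t ε̂ and samples the same
analytic posterior restricted to [0, t] at the previous grid point, which
degenerates to X̂_0 deterministically at t = 0 and is exact end-to-end
when the predictor is exact. The inference grid may be a uniform-stride
subset of the training steps; the default uses all of them.

Time is indexed by integers 0…T and β is treated as a per-step increment,
so the discrete sums coincide with the normalized-time integral reading of
the accumulated variances; no separate continuous-time constant is
introduced.

Reverse updates are applied in pixel space: the network predicts noise in
the packed wavelet domain, the prediction is brought back through the
inverse transform, and the ancestral step operates on the pixel-space
state. Since the transform is an isometry and is re-applied at the next
step, this is numerically equivalent to updating the packed coefficients
directly; the pixel-space form keeps the bridge module independent of the
wavelet module.

## Wavelet domain

All spectral operations use the *orthonormal* Haar filter bank (taps
±1/√2). Orthonormality is chosen (over the averaging 1/2 normalization)
because it makes the transform an isometry: sub-band energy equals pixel
energy, i.i.d. Gaussian noise remains i.i.d. Gaussian with the same σ
across the transform, and the wavelet-domain MSE objective is *identical*
to the pixel-domain one (tested). The high-pass convention is
(first − second)/√2 along each axis; on [[1,2],[3,4]] this gives LL = 5,
LH = −2, HL = −1, HH = 0, and matches PyWavelets' `haar` in
`periodization` mode coefficient-for-coefficient (tested against it as an
independent oracle). Images must have even spatial dimensions at every
level used; odd sizes are rejected rather than padded, so no boundary
extension mode exists to introduce artifacts. Packed layout is the frozen
channel order (LL, LH, HL, HH).

## Denoiser

A U-Net over packed sub-bands: input is the concatenation of packed X_t
and the packed conditional image (8C channels for C-channel images),
output the packed noise (4C). Defaults at desk scale: 2 levels, 16 base
channels, multipliers (1, 2), sinusoidal time embedding of dimension 64
projected into every ResBlock, single-head self-attention at the
bottleneck, GroupNorm throughout, He-style truncated-normal init with
zero-initialized residual/output projections (the network starts by
predicting zero noise, which stabilizes early ε-regression; one optimizer
step opens the zero-initialized paths, which is why the dead-branch test
checks gradients after a warm-up step rather than at exact init).

Encoder downsampling is a wavelet layer: per-channel Haar DWT, the four
sub-bands stacked on channels (4×, half resolution), then a learned 1×1
projection to the next width. The raw packed input is itself Haar-chained
to each downsampled resolution and added through a zero-initialized 1×1
shortcut, so full-bandwidth signal reaches every pyramid level. The
ablation variant replaces this with stride-2 convolution.

The high-frequency supervision module (HFSM) sits at each configured
decoder level k, which has resolution (H/2^k, W/2^k): the conditional
image is decomposed to depth M and level k's detail bands — the only
depth whose resolution matches — are summed (LH + HL + HH) and projected
by 1×1 convolution to the queries; keys and values are independent 1×1
projections of the decoder feature map; attention is single-head over
flattened spatial tokens with scale 1/√d_k, d_k the projected channel
count. The output *augments* the skip connection (concatenated, not
substituted), so disabling HFSM reduces exactly to the plain U-Net skip.
No gradient flows into the conditional image.

## Conditioning

The conditional image is computed once per sample, never re-generated
inside the sampling loop, and never alters the bridge endpoints (X_T is
always the raw source). The default provider is a three-layer residual
convnet fitted with a smoothed-L1 objective (√(d²+1e−6)) on the training
split — a deliberately weak one-shot regressor whose held-out conditioning
error must not exceed the raw source-target gap (tested). The identity
provider serves as the ablation baseline. A large pre-trained generator
can implement the same two-method interface.

## Synthetic phantoms

Each subject is an outer head ellipse, K = 3 inner tissue ellipses and,
in half of subjects, one small focal lesion; a subject's slices share
this geometry up to ~3 % jitter, emulating adjacent slices of a volume.
The two "modalities" render the *same* label map through two contrast
lookup tables (source: head 0.0, tissues 0.35/−0.35/0.15, lesion 0.25;
target: 0.45, −0.15/0.30/−0.30, 0.85; background −1 in both), plus
independent Gaussian noise σ = 0.02 per image. The tables are fixed so
the inter-modality gap inside the head (≥ 0.45 mean absolute difference)
dwarfs the noise floor — the task is a genuine contrast remapping, not
denoising. Splits are 80/10/10 *by subject*.

What the phantoms do **not** emulate: anatomical texture within tissues,
bias fields, partial-volume edges, registration error, k-space artifacts.
Passing the learning tests therefore shows the pipeline learns a
noise-robust cross-contrast mapping with correct geometry handling; it
does not certify performance on real MRI, which additionally needs the
full-scale settings (256×256, T = 1000, a strong conditional generator).

## Problem sizes and numerical choices

The study configuration is 32×32 images, T = 20 steps, batch 2, 2 000
iterations, AdamW with learning rate 1e−3 (β = (0.9, 0.999), decoupled
weight decay 1e−4, skipped for biases and norm parameters), validation
every 250 iterations, best checkpoint by minimum validation loss with
ties to the later iteration. The full-scale defaults (learning rate 5e−5,
batch 2, T = 1000, 256×256) are exposed in `TrainConfig`; the desk preset
uses the larger rate because the network is ~150 k parameters and the
budget short. The default schedule is symmetric-triangular with the peak
chosen so σ_T² = 1 on the normalized intensity scale; the constant
schedule exists for closed-form tests.

Everything runs in float64 on a hand-rolled reverse-mode autodiff engine
(`fadm.nn`): training is then a pure function of the seed and two runs are
bit-identical on the same platform (tested). All randomness flows through
explicit `numpy.random.Generator` objects; there is no global RNG state.
Degenerate inputs are rejected rather than coerced: odd image dimensions,
out-of-range step indices, t = 0 in the ε-target (σ_0 = 0), mis-ordered
reverse steps, unfitted providers, non-finite losses (aborted with the
offending step indices).

PSNR uses data range 2 on [−1, 1] images and caps identical-image pairs
at 100 dB. SSIM uses the universal constants (Gaussian window 11,
σ = 1.5, K1 = 0.01, K2 = 0.03, window radius cropped before averaging)
and is verified against scikit-image's implementation to 1e−4.
Distribution-level metrics that require pretrained feature extractors are
out of scope; the report format reserves a column for one.

## Known limitations

* Wavelet boundary handling is avoided, not solved: sizes must be even at
  every level, and repeated transforms still concentrate error at image
  borders on real data.
* 2D only; adjacent-slice channel stacking is the only 3D context.
* The regression conditioning surrogate is far weaker than a pre-trained
  generative model; ablation gaps measured with it will understate what
  stronger conditioning contributes.
* The numpy engine is single-process and desk-scale by design; full-scale
  (256×256, T = 1000) training belongs on a GPU framework implementing
  the same interfaces.
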