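# fadm — frequency-aware diffusion bridge for paired image translation

`fadm` translates a 2D grayscale image of one acquisition contrast into a
co-registered image of another (the motivating case: cross-modality MRI,
e.g. synthesizing a 3T-quality or T2-weighted slice from a 1.5T or
T1-weighted one). It is aimed at researchers who have *paired*,
co-registered data and want a diffusion-based translator that runs its
denoising in the wavelet domain, at a quarter of the pixel count per step.

## Method

Instead of denoising from Gaussian noise, the model runs a **paired
Schrödinger bridge** between the source image X_T and the target image
X_0. With σ_t² the noise variance accumulated from time 0 to t and σ̄_t²
the variance from t to T, the intermediate marginal is the Gaussian

    q(X_t | X_0, X_T) = N(μ_t, Σ_t),
    μ_t = (σ̄_t² X_0 + σ_t² X_T) / (σ̄_t² + σ_t²),
    Σ_t = σ_t² σ̄_t² / (σ̄_t² + σ_t²) · I,

whose mean interpolates the endpoints and whose variance vanishes at both.
A denoiser is trained to regress ε = (X_t − X_0)/σ_t; reverse sampling
forms X̂_0 = X_t − σ_t ε̂ and draws the analytic posterior of the
sub-bridge on [0, t].

Three frequency-aware ingredients:

* every step works on the four **orthonormal Haar sub-bands** (LL, LH, HL,
  HH) stacked as channels — half resolution, energy preserved exactly, so
  wavelet-domain MSE equals pixel-domain MSE;
* the U-Net encoder downsamples with **wavelet downsampling layers**
  (DWT → channel concatenation → learned 1×1 projection) plus a Haar-
  decomposed raw-input shortcut per level;
* decoder levels apply a **high-frequency supervision module**: cross-
  attention with queries Q = Conv1×1(X_lh + X_hl + X_hh) from the detail
  bands of a conditional image, K and V from the decoder features, output
  softmax(QKᵀ/√d_k)V concatenated with the skip connection.

The conditional image is a one-shot target-like estimate from a pluggable
provider (`identity` or a small fitted `regression` net; a large
pre-trained generator can be slotted in through the same interface).

## Worked example

Train on the built-in synthetic paired phantoms (same tissue geometry,
two contrast tables, additive noise) and evaluate on held-out subjects:

```python
import numpy as np
from fadm import train_sample as ts
from fadm.data import make_dataset, pairs_to_arrays
from fadm.faunet import DenoiserConfig
from fadm.conditioning import RegressionProvider
from fadm.metrics import evaluate_split

splits = make_dataset(n_subjects=20, slices_per_subject=4, seed=0, size=32)
tr_s, tr_t = pairs_to_arrays(splits.train)
prov = RegressionProvider(seed=0); prov.fit(tr_s, tr_t, seed=0)
res = ts.train(ts.desk_train_config(seed=0), DenoiserConfig(),
               (tr_s, tr_t), pairs_to_arrays(splits.val), prov)
te_s, te_t = pairs_to_arrays(splits.test)
gen = ts.sample(te_s, prov, res.net, res.sched, np.random.default_rng(123))
print("generated:", evaluate_split(list(gen), list(te_t)).psnr_mean)
print("source:   ", evaluate_split(list(te_s), list(te_t)).psnr_mean)
```

On one CPU this trains in a couple of minutes and prints

```
generated: 22.817128...
source:    14.830381...
```

i.e. the translated test images are ≈ 8 dB closer to the target modality
than the raw source images are (SSIM improves from −0.07 to 0.55). The
numbers move slightly with the seed; the direction does not.

A thin CLI wraps the same calls: `fadm train --config cfg.yaml --seed 0`,
`fadm sample --checkpoint ck/best.npz --input src.png --output out/`,
`fadm evaluate --generated out/ --reference ref/ --report report.tsv`.
Real co-registered volumes can be sliced with
`fadm.data.load_volume_slices` (NIfTI, axial/coronal/sagittal, optional
adjacent-slice channel stacking).

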