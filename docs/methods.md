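# Methods

## Problem and model

`colposeg` segments the cervix region of interest (ROI) from colposcopy
images with no annotations at any stage.  The segmenter is a **W-Net**: two
U-Nets in series forming an autoencoder.  The *encoder* U-Net maps an RGB
image `x ∈ [0,1]^{H×W×3}` to a per-pixel class-probability map
`r' ∈ [0,1]^{H×W×K}` (channel softmax, rows summing to 1); the *decoder*
U-Net maps `r'` back to a reconstruction `x'`.  Three training objectives
are involved:

- **CT-loss** (encoder objective of the proposed method):
  `L_CT = L_CE(r', c) + λ · L_TV(r')`, where `c = argmax_k r'` is the
  *pseudo segmentation mask* — recomputed at every optimization step and
  treated as a constant (gradient-detached) — and `L_TV` is anisotropic
  total variation (L1 differences over horizontal and vertical neighbour
  pairs).  Cross-entropy sharpens the map toward its own labels; total
  variation favours spatially compact regions.
- **Soft N-cut loss** (encoder objective of the graph-cut W-Net baseline):
  `K − Σ_k (Σ_{u,v} w(u,v) p_k(u) p_k(v)) / (Σ_{u,v} w(u,v) p_k(u))` with
  Gaussian colour/space affinities `w` truncated at a spatial radius, after
  average-pooling image and response to reduce the quadratic cost.
- **Reconstruction loss** (full-network objective): mean squared error
  between `x` and `x'`.

**Encoder-weighted (EW) learning** repeats cycles of `i` encoder-only
epochs minimizing the encoder objective at a small rate `η_enc`, followed
by one full-autoencoder epoch minimizing the MSE at a larger rate
`η_entire`.  `i = 1` is exactly the classic alternating W-Net procedure.
After every cycle the mean **confidence score** (average per-pixel maximum
probability) over the un-augmented training images is recorded; the
returned model is the checkpoint with the best confidence (earliest on
ties).  The third compared method is per-image **CNN feature clustering**:
a small fully convolutional network self-trained on a single image for `T`
iterations under the same CE + TV objective (the loss functions are shared
code, not re-implementations).

## Defaults and their origins

| parameter | default | note |
|---|---|---|
| classes K | 2 | cervix vs non-cervix |
| encoder epochs per cycle i | 7 | ablation optimum |
| η_enc | 7e-5 | Adam; encoder steps |
| η_entire | 1e-3 | Adam; full-network steps (all parameters) |
| max epochs | 500 | every epoch of either kind counts |
| batch size | 4 | unstated upstream; 1/2/10 tried, none better |
| tv weight λ | 1.0 | unweighted sum of the two CT terms |
| filters, baseline | (64,128,256,512) | depth 4 |
| filters, shallow | (64,128,256) | depth 3, used with EW |
| soft N-cut σ_I, σ_X, r, pool | 10 (0–255 scale), 4, 5, 2 | original W-Net convention |
| CNN method M, width, T, μ, lr | 3, 100, 500, 1.0, 0.05 (SGD, momentum 0.9) | source-method style defaults |
| augmentation | h/v-flip p=0.5 each, blur p=0.5 with σ~U[0,1.5] | fresh random view per image per epoch |

Block structure (each level `[3×3 conv → batch norm → ReLU] × 2`, 2×2 max
pool down, 2×2 transposed conv up, concatenation skips, 1×1 head) is a
standard U-Net dialect; exact parameter counts of the original
implementations are not reproduced, and none of the published parameter
counts are targets here.

## Loss-scale normalization

The CT-loss is printed as an unweighted sum, but its two terms scale
differently with image size: per-pixel cross-entropy versus a
total-variation sum over all neighbour pairs.  The loss *functions* keep
the literal contracts (CE mean over pixels; TV sum over pairs, with a
`strict_bounds` flag for the literal truncated summation and a `reduction`
option on both).  The *training loops* normalize both terms per scalar
element (CE mean over pixels, TV mean over difference terms) so the
objective scale — and hence the printed learning rates — transfers across
resolutions; the source CNN-clustering method averages both terms the same
way.  A raw-sum TV at 64×64 outweighs mean CE by three orders of magnitude
and collapses the response map to a constant; a per-pixel TV
(`tv_weight ≈ 4` in mean units) was also evaluated and degraded recovery
on 2 of 3 seeds, so the weaker term-mean normalization is the default.

Adam is used for both parameter groups with independent moment states, so
the encoder objective's moments are not contaminated by reconstruction
steps.  Probabilities are clamped at 1e-8 in the log; NaN anywhere aborts
training with the epoch/batch in the raised error and the trace attached.

## Synthetic data

The generator emulates the *structure* of colposcopy frames, not their
appearance: one roughly central, randomly rotated anti-aliased ellipse
(pink-ish foreground ≈ cervix) over a darker red-brown background, Gaussian
texture noise (sd 0.05), and a few near-white discs emulating specular
glare.  Glare discs are painted after the mask and are *not* excluded from
it, mirroring real glare inside the cervix region and stressing robustness
to outlier pixels.  Default foreground/background means are ≥ 0.3 apart in
every channel, so a per-pixel colour threshold alone achieves ≥ 0.95 Dice —
the task is deliberately easy, making segmentation failures attributable to
the method rather than the data.  What the generator does **not** model:
speculum and vaginal-wall geometry, aceto-white lesions, green-filter or
iodine appearance, camera vignetting, inter-image illumination shifts.
Passing tests on this data demonstrate mechanism correctness, not clinical
performance.

## Problem sizes used in tests and the acceptance script

Desk-scale study conditions: 10 synthetic 64×64 images, the shallow filter
pyramid scaled to (16, 32, 64), 150-epoch budget, training seeds 0/1/2.
Oracle checks run at ≤ 8×8 (all-pairs soft N-cut, sign-assignment Wilcoxon
enumeration, finite-difference gradients on float64 models).

## Known limitations

- **Initialization sensitivity.**  The CT objective contains no
  image-dependent term: cross-entropy amplifies whatever partition the
  randomly initialized encoder produces, and colour alignment enters only
  through the reconstruction epochs.  At desk scale the decoder
  reconstructs nearly as well from a misaligned partition as from an
  aligned one (the per-epoch reconstruction losses are in the training
  trace), so some seeds converge to sharp but misaligned segmentations:
  in the 10-image recovery study some training seeds exceed 0.95 mean
  best-label Dice while others plateau below 0.8 — the per-seed values are
  printed by the recovery check in the test suite.  The EW schedule (i=7)
  consistently outperforms the i=1 alternation on the same seeds.  Longer
  training does not rescue a misaligned seed — confidence keeps rising
  while Dice can fall (entrenchment) — which is precisely the
  initial-pseudo-mask dependence that motivates EW learning.
- **Confidence is not Dice.**  Model selection by mean confidence prefers
  sharp maps, aligned or not; it is the right annotation-free criterion but
  gives no accuracy guarantee.
- The soft N-cut affinity uses a fixed radius and scales; no CRF
  post-processing, multi-scale affinities, or superpixel refinement.
- Single-device, single-precision training; no learning-rate schedules or
  weight decay.
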