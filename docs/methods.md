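# Methods

## Model

ACAU-Net is a binary semantic-segmentation network for disc-centered fundus
crops.  Its structural commitments are:

* **Dense connectivity in the encoder.**  Within a dense block, layer *l*
  computes `u_l = H_l([u_0, …, u_{l−1}])`, where each `H_l` is
  norm–ReLU–1×1-conv (a bottleneck of `bn_size · growth` channels) followed
  by norm–ReLU–3×3-conv producing `growth` channels.  The concatenation
  makes the output width exactly `C_in + L · growth` — a contract the tests
  assert for every configuration.  Residual blocks
  (`u_l = H_l(u_{l−1}) + u_{l−1}`) are provided as a library primitive.
* **Channel attention in the decoder.**  Each ACAU stage treats the encoder
  skip `x_l` as carrying spatial detail but unreliable semantics, and the
  coarser decoder stream `x_h` as carrying semantics.  Two multiplicative
  channel gates, both in (0,1), modulate the skip: a squeeze-and-excitation
  gate computed from `x_l` itself (global average pool, two fully connected
  layers with reduction ratio `r`, sigmoid), and a GeM-pooled descriptor of
  the channel-matched, rectified `x_h` passed through a sigmoid.  The gated
  skip is concatenated with the transposed-convolution-upsampled `x_h` and
  fused by a 3×3 convolution.
* **Multi-scale context at the bottleneck.**  Dense atrous convolution
  (parallel dilated 3×3 branches, ReLU, summed onto the residual input;
  all-zero branches reduce to the identity) followed by residual
  multi-kernel pooling (per-size max-pool → 1×1 conv to one channel →
  bilinear upsample → concatenation, +1 channel per pool size).
* **Single-channel sigmoid head.**  The task is binary, so the prediction
  head is deconvolution–ReLU–3×3-conv–sigmoid; a two-channel softmax head
  would be an equivalent parameterisation and is intentionally not
  duplicated.

Assumptions: inputs are disc-centered square RGB crops whose sides are
divisible by 32; masks are strictly binary; one connected bright disc per
image (nothing enforces this, but the synthetic generator and the loss
defaults are tuned for small-foreground images).

## Parameters

| name | default | meaning / rationale |
|---|---|---|
| `growth_rate`, `layers_per_block` | 32, (6,12,24,16) | DenseNet-121 geometry, the standard dense encoder; reduced profile 8, (2,2,2,2) for CPU-speed runs |
| `se_reduction` (r) | 16 (tests 2) | SE bottleneck ratio, the standard choice; must divide every gated skip width |
| `pk` | 5 | GeM exponent (dimensionless, ≥ 1); 1 = average pooling, large → max pooling; 5 weights strong activations without collapsing to max |
| `dac_dilations` | (1,3,5) | dilation set of the bottleneck branches; padding = dilation keeps shape |
| `rmp_pool_sizes` | (2,3,5,6) | pooling windows (pixels) at the bottleneck; the reduced profile uses (1,2) because its bottleneck is 2×2 |
| `alpha` | 0.5 | blend of cross-entropy vs dice complement; 1 = pure CE, 0 = pure dice |
| `smooth` (S) | 1.0 | add-one smoothing of the dice ratio; defines the empty-vs-empty case as perfect overlap |
| `base_lr` | 2e-4 | Adam base step of the full-scale protocol (200 epochs, ~10³ images) |
| `poly_power` | 0.9 | exponent of the poly decay `(1 − iter/max_iter)^power`, applied per optimizer step |
| `batch_size` | 1 | the full-scale protocol's setting; descriptors are per-sample, so larger batches change nothing but throughput |
| `threshold` | 0.5 | probability cut for hard masks; ties go to foreground |
| `clip_eps` | 1e-7 | log-argument clamp in the cross-entropy (the loss is unbounded at p ∈ {0,1}) |

**Desk-scale training** (`desk_scale_train_config`): 8 synthetic 64×64
pairs, 200 optimizer steps, `base_lr = 0.03`, no held-out split.  The
full-scale learning rate is tied to a budget of ~200k steps; within 200
steps Adam at 2e-4 cannot leave the all-background basin that heavily
imbalanced CE creates, so the desk profile uses the larger step.  All
reported desk-scale numbers (tests and `scripts/acceptance.py`) use these
problem sizes.

## Synthetic data

The generator emulates the features of disc-centered fundus crops that the
model actually exploits: a bright quasi-elliptical disc (radius a
configurable fraction of the side, jittered center, mild eccentricity,
soft rim) on a darker low-frequency reddish texture, dark Bézier vessel
curves crossing the frame near the disc, and additive Gaussian noise.  The
mask is the exact rendered disc support, so label noise is zero.

It does **not** emulate pathology (exudates, peripapillary atrophy),
camera vignetting, the fundus border, resolution anisotropy, or
inter-annotator variability.  Passing the desk-scale tests therefore
demonstrates that the architecture, losses, gradients and training loop
are correct and that the network can represent and learn the disc-on-
background decision; it says nothing about clinical performance on real
fundus datasets.

## Numerical choices

* **Normalisation.**  Per-sample instance normalisation by default.  With
  batch size 1, batch statistics *are* instance statistics during training,
  but running-average evaluation statistics then diverge from what the
  network was trained with; instance norm makes training and inference
  identical and keeps batch elements independent (the batch-permutation
  invariance test relies on this).  Batch norm remains available
  (`norm="batch"`).
* **GeM stability.**  `x^pk` overflows float32 for large `pk`; GeM is
  computed as `m · (mean((x/m)^pk))^{1/pk}` with `m` the per-channel max.
  Because GeM is positively homogeneous of degree 1, holding `m` constant
  in the backward pass still gives the exact gradient (Euler's theorem).
  `pk = 1` short-circuits to the exact mean.  Inputs are rectified before
  pooling so fractional powers are defined.
* **Transposed convolution** is implemented as the exact adjoint of the
  strided im2col convolution (scatter-add col2im), which makes the
  gradient pair self-consistent by construction.
* **Degenerate inputs.**  Empty ∪ empty masks define `E = 0`; the smoothed
  dice of two empty masks is 1.  Cross-entropy clamps probabilities to
  `[1e-7, 1 − 1e-7]`.  A pooling window larger than the spatial extent, a
  non-divisible input size, an SE ratio that does not divide a gated width,
  and non-binary ground truth all raise immediately with the offending
  quantity named.
* **Determinism.**  All randomness flows through `numpy.random.Generator`
  seeded from configs; sample `i` of a synthetic dataset is seeded by
  `(seed, i)` independently, so datasets are stable under re-indexing.
  Two builds from the same seed are bit-identical, as are two training
  runs.

## Design choices where the architecture was open

* **Skip tap points**: after each dense block, before the transition; the
  stem output (1/2 resolution) supplies the finest skip.
* **ACAU merge order**: the attention product is formed at skip
  resolution, then concatenated with the 2×-upsampled high-level path
  (transposed conv by default, bilinear as a config switch) and fused to
  the stage width by a 3×3 convolution.
* **Stem pooling**: a 3×3/2 max-pool follows the stem so encoder
  resolutions match standard dense-feature pyramids (total downsampling
  32).
* **Transition compression** 0.5, dense-layer bottleneck `bn_size` 4 — the
  standard dense-encoder settings.
* **Eightfold augmentation**: "horizontal, vertical and diagonal flips"
  generate the full 8-element dihedral orbit of the square — the only
  composition of those flips that yields exactly an 8× expansion.
  Orientation expansion is deterministic and offline; photometric jitter
  (brightness scaling and small translations) is random and online.
* **Dataset resizing** stretches to the target square rather than padding
  (masks nearest-neighbour to stay binary).
* **`pk` is a fixed hyper-parameter**, not learned; the sweep command
  exists to reproduce the tuning-curve shape at desk scale.

## Known limitations

* No GPU path: the numpy backend trains the reduced profile in seconds but
  full-profile 448×448 training at publication scale is out of reach
  (a single full-profile forward pass takes ~6 s on one CPU core).
* Encoder pretraining is not bundled; `pretrained_encoder` accepts an
  external `.npz` state dict with matching shapes but no converter from
  other frameworks is provided.
* Binary segmentation only; no multi-class head, no cup segmentation, no
  cup-to-disc-ratio computation.
* The holdout overlap error reported by the acceptance script measures
  generalisation across draws of the *synthetic* distribution only.
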