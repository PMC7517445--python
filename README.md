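# acaunet

Optic-disc segmentation of fundus photographs with an **aggregation channel
attention U-Net (ACAU-Net)**: a densely connected encoder, a multi-scale
dilated-convolution bottleneck, and a decoder whose upsampling stages use
channel attention aggregated across resolutions.  The package ships a
synthetic fundus-image generator with exact ground-truth masks, so the whole
pipeline — data, training, evaluation — runs end to end on a laptop CPU with
no dataset download.

**Who is this for?**  Researchers in retinal image analysis who want a
self-contained, fully tested reference implementation of the
attention-gated dense segmentation architecture and its compound loss, and
anyone who needs a reproducible segmentation testbed that does not depend
on restricted clinical data.

## The model

The network is an encoder–bottleneck–decoder of the U-Net family:

* **Encoder** — a 7×7/2 stem followed by four dense blocks
  (layer *l* receives the concatenation `[u_0, …, u_{l−1}]`, so a block with
  *L* layers and growth rate *g* maps `C` channels to `C + L·g`), with
  1×1-conv + 2×2-avg-pool transitions between them.  Total downsampling is
  32.
* **Bottleneck** — dense atrous convolution (parallel 3×3 branches at
  dilations 1/3/5 summed on a residual path) and residual multi-kernel
  pooling (max-pools at several window sizes, each reduced to one channel
  and upsampled back, concatenated to the input).
* **Decoder** — four **aggregation channel attention upsampling (ACAU)**
  stages.  Each stage gates the same-resolution encoder skip `x_l` twice:

  * squeeze-and-excitation: `v_l = GAP(x_l)`,
    `v_o = σ(W₂ δ(W₁ v_l))`, `y_l = v_o ⊙ x_l`
    (σ = sigmoid, δ = ReLU);
  * generalized-mean (GeM) guidance from the coarser decoder features
    `x_h`: after a channel-matching 1×1 convolution and rectification,
    `v_h,c = (mean_i x_h,c(i)^{p_k})^{1/p_k}` and
    `x_out = σ(v_h) ⊙ y_l`.

  The exponent `p_k ≥ 1` interpolates between average pooling (`p_k = 1`)
  and max pooling (`p_k → ∞`); the default is `p_k = 5`.  The gated skip is
  concatenated with the 2×-upsampled (transposed-convolution) high-level
  path and fused by a 3×3 convolution.
* **Head** — deconvolution, ReLU, 3×3 convolution, sigmoid: a per-pixel
  disc probability map at the input resolution.

Training minimises the compound loss

```
L = α · CE + (1 − α) · (1 − (2 Σ pᵢtᵢ + S) / (Σ pᵢ + Σ tᵢ + S))
```

with blend weight `α = 0.5` and add-one smoothing `S = 1`, under Adam with
poly learning-rate decay `lr = base_lr · (1 − iter/max_iter)^0.9`.
Evaluation uses the overlap error `E = 1 − |X∩Y| / |X∪Y|` (one minus IoU;
lower is better).

The network runs on a small reverse-mode autodiff engine written on numpy
(`acaunet.grad`): im2col convolutions dispatched to BLAS, exact adjoint
transposed convolutions, finite-difference-validated gradients throughout.

## Worked example

Fit the reduced profile (growth 8, blocks 2/2/2/2, 64×64 inputs) on eight
synthetic fundus images via the sklearn-style estimator:

```python
from acaunet import ACAUNetSegmenter
from acaunet.synthetic import SyntheticSpec, generate_dataset, to_batch

pairs = generate_dataset(SyntheticSpec(size=64, seed=0), 8)
X, y = to_batch(pairs)                     # (8,3,64,64), (8,64,64)
seg = ACAUNetSegmenter(seed=0).fit(X, y)   # 200 Adam steps, ~15 s on a CPU
print("iterations:", seg.n_iter_)
print("final loss: %.4f" % seg.history_["loss"].iloc[-1])
print("mean IoU on training pairs: %.4f" % seg.score(X, y))
```

prints

```
iterations: 200
final loss: 0.0057
mean IoU on training pairs: 0.9873
```

final loss is the blended dice/cross-entropy objective after the last
optimizer step, and the mean IoU of 0.9873 corresponds to a mean overlap
error E ≈ 0.013 on the images the model was fit to — the network has
recovered the disc masks almost exactly.

The same pipeline is available from the shell:

```bash
acaunet generate --n 16 --size 64 --seed 7 --out data/
acaunet train    --data data/ --out run/ --epochs 25
acaunet evaluate --data data/ --checkpoint run/checkpoint.npz --out metrics.csv
acaunet sweep    --data data/ --pk 1,5,100 --alpha 0,0.5,1 --out sweep.csv
```

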