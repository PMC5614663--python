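# Methods

## Problem and model

`gpdnet` classifies 32×32 RGB gastroscopy-style images into three gastric
precancerous disease (GPD) classes — erosion, polyp, ulcer — with a
deliberately compact convolutional network, and implements two analyses of
that network's weights: an iterative prune-and-retrain fine-tuning loop and
a weight-magnitude ablation study.

Two fixed architectures are provided.

**Fire variant** (14,368 kernel weights at 3 classes):

```
conv 3→32, 5×5, pad 2, ReLU          2,400 weights
maxpool 3×3 / 2                      (32→16)
fire: squeeze 32→16 (1×1), expand 16→32 (1×1) ∥ 16→32 (3×3)   5,632
avgpool 3×3 / 2                      (16→8)
fire: squeeze 64→16 (1×1), expand 16→32 (1×1) ∥ 16→32 (3×3)   6,144
avgpool 3×3 / 2                      (8→4)
conv 64→3, 1×1                         192
global average pool → softmax
```

A fire module is the SqueezeNet building block: a 1×1 "squeeze" convolution
feeding parallel 1×1 and 3×3 "expand" branches whose outputs concatenate
channel-wise (1×1 block first — a fixed convention). Because the head is a
1×1 convolution plus global average pooling rather than dense layers, the
network is fully convolutional and accepts any input ≥ 32×32.

**Baseline** (144,928 kernel weights): the Caffe CIFAR-10-quick network —
three 5×5 convolutions (3→32→32→64) with max/avg/avg pooling, dense
1024→64→3 — with only the output width changed to 3. The two published
counts, and the ~10.0× bias-inclusive reduction ratio (145,123 / 14,563),
are reproduced exactly by `count_parameters`.

The fire variant's internal channel sizes are not uniquely determined by a
prose description; the configuration above is fixed by exact count
matching: 2,400 + 5,632 + 6,144 + 192 = 14,368 is the unique assignment
consistent with "two traditional convolutions and two fire modules" and the
published total. Counts are reported **bias-free by default** because that
convention reproduces both published totals; `include_bias=True` gives the
full tally.

## Numerical engine

No deep-learning framework is used: the networks are small enough that an
im2col + BLAS-matmul NumPy implementation (`gpdnet._layers`) trains them in
seconds to minutes on one CPU core. Details that matter:

- Convolutions are stride-1; gradients w.r.t. inputs are computed as a
  transposed convolution (flipped, channel-swapped kernel), and the first
  layer skips its input gradient.
- Pooling uses ceil-mode output sizing with edge padding (the Caffe
  convention), so 32 → 16 → 8 → 4 under window 3 / stride 2. Max-pool
  backward routes each output's gradient to its argmax (first index on
  ties); average pooling divides by the count of valid (non-padded) pixels.
- The backward pass is verified against central finite differences in
  float64 in the test suite. ReLU is non-differentiable at 0; the check
  offsets biases from zero so no pre-activation sits exactly on the kink.
- Weights are float32; Xavier/Glorot-uniform kernels
  (bound √(6/(fan_in+fan_out))), zero biases, seeded via
  `numpy.random.default_rng` — bit-reproducible per seed.

## Training

Mini-batch SGD on the summed negative log-likelihood
Loss = Σᵢ −log P(lᵢ | Xᵢ; (W, b)). The optimizer divides gradients by the
batch size, so reported epoch losses follow the sum convention while update
magnitudes are batch-size-invariant. Defaults (all exposed on
`TrainConfig`):

| parameter    | default | note |
|--------------|---------|------|
| batch size N | 32      | |
| base_lr      | 0.001   | "step" decay ×0.1 every 20 epochs |
| momentum     | 0.9     | see below |
| weight_decay | 0.004   | L2, kernels only |
| epochs       | 50      | |

The source description of the optimizer sets a "weight decay" of 0.9, which
would make training impossible as an L2 coefficient; we read it as the
momentum coefficient (its conventional value) and keep the
CIFAR-10-quick L2 decay of 0.004. Both are configurable.

Inputs are standardized per channel with training-set statistics — the
compact network barely trains on raw [0,1] gastroscopy-like images because
the large DC component dominates the first-layer gradient. The
standardization is **folded exactly into the first convolution**
(W′ = W/σ, b′ = b − Σ W′μ) when training finishes, and unfolded when a
pretrained model is passed back in, so stored weights always operate on raw
[0,1] images and `forward` needs no preprocessing state. A visible side
effect: the deployed first-layer kernels are ~1/σ ≈ 10× larger than their
in-optimizer scale, which populates the top magnitude bins of the
sensitivity analysis.

Accuracy is top-1; ties resolve to the lowest class index, so an all-zero
(or constant) network scores exactly one class's share of the test set.
Cross-entropy floors probabilities at 1e-12 to keep confidently-wrong
predictions finite.

## Iterative reinforced learning (IRL)

One IRL iteration: set every kernel weight with |w| ≤ threshold to exactly
zero (inclusive comparison; default threshold 0.001), then retrain with the
modified model as the pretrained start, reusing the full epoch budget.
Iteration 0 is the scratch training. Unlike dense-sparse-dense training
there is **no sparsity mask** — zeroed weights relearn freely. Biases are
exempt by default (`apply_to_biases=False`) to match the kernel-only
counting convention. Per-iteration seeds are derived as base_seed + k, so a
run is reproducible but data order differs across iterations; with
threshold 0 the loop is exactly continued training. The threshold sweep
shares a single scratch model across thresholds, so its iteration-0 row is
constant.

## Magnitude sensitivity analysis

Kernel weights are binned by |w| into ten uneven half-open sub-ranges
[0, 0.001), [0.001, 0.005), [0.005, 0.01), [0.01, 0.05), [0.05, 0.1),
[0.1, 0.15), [0.15, 0.2), [0.2, 0.3), [0.3, 0.4), [0.4, ∞) — uneven because
trained weights concentrate near zero. Each bin is ablated independently
(always starting from the intact model) and the ablated model is re-scored
on the fixed test set. The top bin is open-ended rather than capped at 1:
nothing in the model bounds |w| by 1, and folding the input standardization
into the first convolution routinely produces weights above 1 (a warning is
logged). Empty bins are reported with baseline accuracy (ablating nothing
is the identity).

## Synthetic data generator

Real gastroscopy images are private, so `generate_synthetic_gpd` renders
procedural stand-ins on a mucosa-like pink-red field with smooth
low-frequency color variation: **erosion** = 7–12 small irregular reddish
patches; **polyp** = a bright circular protrusion with radial shading and a
specular highlight; **ulcer** = a dark crater rim around a pale center.
Difficulty presets scale additive Gaussian pixel noise (σ = 0.04 / 0.22 /
0.34 for easy / medium / hard), geometric jitter (2 / 5 / 7 px), and lesion
contrast (1.0 / 0.45 / 0.28). The presets are calibrated so that: the easy
preset is separable to > 0.9 accuracy within a 10-epoch budget; the medium
preset leaves clear headroom for IRL refinement (scratch accuracy well
below ceiling at short budgets); and accuracy orders easy ≥ medium ≥ hard
on matched budgets.

What the generator does **not** emulate: specular/fluid artifacts, vignetting,
camera pose and illumination variation, inter-patient texture diversity,
class-ambiguous lesions, and label noise. Passing tests therefore
demonstrate that the architecture, optimizer, pruning loop and ablation
analysis behave as specified — not that the network reaches any particular
accuracy on clinical images.

The augmentation module mirrors the source protocol in shape: random square
crops (configurable ROI sizes; clinical-scale defaults 475/400/320 with
±10 px translation) resized bilinearly to 32×32, with either a uniform
multiplier or exact per-class output totals (the clinical counts
388→1,211, 467→1,218, 476→1,244 are a supported configuration). The split
protocol shuffles per class and holds out a fixed count (default 300) per
class — an exact partition.

## Problem sizes used by the test suite

The prune-and-retrain study in the test suite runs the medium preset at 200
images/class (100/class held out), 15-epoch budget, threshold 0.001, 6
iterations, 3 seeds — a scale chosen so the full 3-seed study completes in
minutes on one CPU while leaving the directional conclusions (refinement
helps; large weights matter more) intact. The acceptance script's parameter
counts are architecture arithmetic and run in under a second.

## Known limitations

- Stride-1 convolutions only (both variants use stride 1 throughout).
- Single-threaded-CPU determinism: bit-reproducibility assumes a fixed
  BLAS configuration; across BLAS builds results may differ in the last ulp.
- The generator's classes are far cleaner than clinical data; absolute
  accuracies on it say nothing about clinical performance.
- Serialized model size and wall-clock inference timing are out of scope.
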