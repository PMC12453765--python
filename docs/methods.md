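# Methods

## Problem and scope

Single-cell crops from stained peripheral blood smears are classified as
normal leukocytes or leukemic blasts. The package implements the full
method stack — contrast enhancement, the PIDSAN4 hybrid network, a
modified ViT-Tiny/16, grey-wolf hyperparameter search, class-weighted
training and the standard evaluation statistics — and validates it end to
end on synthetic data. It does not ship trained weights and does not try
to reproduce accuracies reported on the public C-NMC-style dataset, which
require the external images and long GPU training.

## Contrast enhancement

Images are normalised to [0, 1] before any stage; applying `sinh` to raw
8-bit values would be meaningless, and dividing by `sinh(1)` keeps the
codomain in [0, 1]. The four stages are:

1. `sinh(f)/sinh(1)` — strictly increasing, expands bright structure more
   than dark.
2. `ρ·x^α` clipped to [0, 1]; defaults ρ = 1.0, α = 0.9 (a mild mid-tone
   lift; both are exposed and searchable).
3. Dehazing `(I − ω_A)/ε_t + ω_A`. The airlight `ω_A` and transmission
   `ε_t` estimators follow the dark-channel-prior convention: dark channel
   = windowed minimum over channels and a `window`×`window` neighbourhood
   (default 15, edges clamped); `ω_A` = mean colour of the brightest
   0.1% of dark-channel pixels; `ε_t = 1 − 0.95·darkchannel(I/ω_A)`
   clamped to [0.1, 1]. The floor prevents division blow-up.
4. Min–max stretch. A constant image maps to all zeros rather than NaN —
   a deliberate, testable convention for the degenerate case.

Stages 1, 2 and 4 run per channel; dehazing shares one transmission map
across channels with a per-channel airlight. Single-channel images skip
the (colour-based) dehazing stage.

## PIDSAN4

Stem: 3×3 conv stride 2 → 32 channels, then 3×3 stride 1 → 64 channels,
each followed by batch norm and the configurable stem activation (default
ReLU; this is the activation the hyperparameter search varies — the
bottleneck branches always use swish, which is part of the block design).
Four stages follow, each `section_depth` inverted-bottleneck blocks then
2×2 max pooling + swish. A block runs two parallel branches of
1×1 expansion conv → BN → swish → 3×3 depthwise conv → BN → swish →
1×1 projection, sums the branch outputs elementwise and adds the block
input (the parallel-merge rule is a design choice; it preserves shapes
and the skip formula).

For a 224×224 input the trunk ends at 7×7, which cannot tile into 16
square patches; the map is bilinearly resampled to 8×8 (align-corners)
and split into a 4×4 grid of 2×2 patches — 16 tokens, each flattened and
affinely projected to the embedding width (default 64, matching the
projection depth). Spatial self-attention runs over the 16 tokens and
channel attention over the transposed sequence; both are single-head
scaled dot-product attentions with learned Q/K/V maps. The fusion
`φ_E + α·s + β·c` uses trainable scalars initialised at 0.5. Head:
global average pool over tokens → dropout (the searched rate; the layer
sits before the final fully connected layer) → softmax.

`describe()` reports the enumerated parameter count of whatever
configuration was instantiated (the default is ≈123k); no attempt is made
to match any externally quoted figure.

## Modified ViT-Tiny/16

Standard tiny16 shape: patch 16, width 192, 3 heads, 12 pre-norm encoder
layers with GeLU MLPs (ratio 4), a learnable class token and a learned
1-D positional table (init N(0, 0.02²)). The modified head replaces the
class-token readout with layer norm → global average pooling over all
m + 1 tokens (class token included, retained for architectural fidelity)
→ fully connected → softmax. Weight loading/saving uses the same
checkpoint contract as PIDSAN4; random init is the tested default.

## Numerical core

No deep-learning framework is used; `pidsan.nn` is a compact reverse-mode
autograd on NumPy arrays: broadcasting arithmetic with gradient
un-broadcasting, batched matmul, a fused numerically stable softmax,
im2col convolution with channel groups (backward via col2im scatter), and
argmax-routed 2×2 max-pool gradients. Correctness is enforced by central
finite-difference tests (relative tolerance 1e-4) at the op level and
through the whole PIDSAN4 and ViT graphs. Models default to float64;
training configurations use float32 for speed. Batch norm uses eps 1e-5,
momentum 0.1; conv weights are He-initialised, linear layers Xavier-style
with a 0.1 scale on classifier heads so training starts near the uniform
prediction. All initialisation is driven by a single model seed.

After a short training run the exponential running statistics of batch
norm lag the final weights, which wrecks eval-mode predictions; the
training loop therefore finishes with a recalibration pass that replaces
them with the exact average of per-batch moments over the training set
(cumulative moving average with frozen weights).

## Grey wolf optimization

Positions live in internal [0, 1] coordinates; each dimension decodes to
its native range — log scale for learning rate and L2 (their ranges span
3–6 decades), linear for dropout, linear + round-to-integer (floor 1) for
section depth, and `floor(u·n_labels)` for the categorical activation.
Per wolf and leader, `Φ = |C₂·ω_leader − ω|` with C₂ ~ U[0, 2] and the
proposal is `ω_leader − C₁·Φ` with C₁ ~ U[−τ, τ]; the new position is the
mean of the three proposals, clamped to bounds. τ decays linearly from 2
to 0 across the iteration budget, moving the pack from exploration to
convergence on the leaders. Leaders are the three best-ever evaluated
positions (archive semantics), which makes the best-so-far history
monotone; ties break toward earlier discovery. Defaults: 10 wolves
(packs of five to twelve are conventional), 20 iterations; the objective
is called at most `n_wolves·(max_iter+1)` times, a failing or non-finite
evaluation scores −∞ and the run continues.

## Training and evaluation

Class weights are `w_c = T/(C·n_c)` recomputed from the training-label
counts each run; with counts (5531, 5530) this is (0.9999096, 1.0000904).
The loss is class-weighted categorical cross-entropy on the softmax
probabilities, clamped at 1e−12 before the log so a zero probability at
the true class is a large finite loss. The optimizer is SGD with momentum
0.9 (momentum unstated elsewhere; 0.9 is the convention) and optional L2;
a global gradient-norm clip (default 5.0) guards the short-run regime.
Splits are stratified by class label only — the public folder layout does
not encode the 118-patient provenance, so patient-level leakage control
is impossible on such data and results on it should be read accordingly.
Three-way percentage splits use per-class largest-remainder allocation
(exact partition, per-class proportions within one sample); k-fold plans
delegate to stratified k-fold from scikit-learn.

Metrics use the standard formulas; zero-denominator ratios are reported
as 0 with a warning flag. Note that published tables computed with other
conventions may not satisfy `G = √(sens·spec)` or the harmonic-mean
F-measure exactly; this package always uses the standard formulas. For
the CI arithmetic, `SEM = √(p(1−p)/N)` at N = 2,131 yields 0.00664 for
p = 0.895 and 0.00696 for p = 0.883 — close to, but not identical with,
externally quoted SEMs of 0.00665 and 0.00698; the binomial values are
the ones the tests assert. Gaussian noise levels are interpreted as σ in
percent of the [0, 1] dynamic range (the natural reading when none is
given), applied per image with per-image seeds and clipped.

## Synthetic data and the benchmark

Each image is one central white cell on a light background with red-cell
distractors: a Fourier-perturbed ellipse (low-order harmonics, amplitude
larger for blasts), an inner nucleus whose area ratio is drawn from
N(0.35, 0.05²) for normal cells and N(0.70, 0.08²) for blasts —
non-overlapping at ±2σ, so the class signal is learnable by construction
— plus chromatin texture and additive noise (σ 0.02). The signal is
geometric rather than colour-only so both the convolutional and the
attention paths carry usable features. The generator is deterministic
under its seed and writes lossless PNG for on-disk fixtures.

The end-to-end benchmark (`pidsan.protocols`) uses 200 images (100 per
class) at 64×64 — the package's CPU-scale study size; the architectures
are size-generic, and the reduced widths (stem 8/16, embedding 16 for
PIDSAN4; depth 2 at width 192 for the ViT) keep a three-seed run in the
low minutes — split 70:20:10, trained 10 epochs. Recipes: PIDSAN4
lr 0.005, batch 16, clip 5.0; ViT lr 0.05, batch 16, clip 0.5 (a
transformer head needs the larger step to move in 10 epochs; the tight
clip keeps it stable). Median held-out accuracy over seeds (1, 2, 3) is
0.95 for PIDSAN4 and 0.775 for the ViT.

What passing this benchmark shows: the full pipeline — generation,
enhancement-compatible images, forward/backward through both
architectures, weighted loss, the optimizer, splits, metrics — is wired
correctly and can extract a known morphological signal. What it does not
show: performance on real stained smears, which have patient-level
variation, staining artefacts, overlapping cells and far subtler
morphology than the generator produces.

## Known limitations

- The autograd engine is single-threaded NumPy; full-width 224×224
  training is possible but slow, and no GPU path exists.
- Trained models can be brittle under noise levels beyond those seen in
  training (accuracy at 5% noise varies widely across seeds), which the
  robustness protocol exposes rather than hides.
- The categorical activation dimension uses continuous relaxation with
  floor decoding; for three labels the search granularity is coarse.
- The synthetic generator is not a biophysical smear simulator and
  provides no segmentation ground truth beyond per-cell nucleus ratios.
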