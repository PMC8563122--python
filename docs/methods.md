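# Methods

## The model

`palmdx` implements a two-task convolutional classifier for palm
photographs: task M detects metacarpophalangeal-joint (knuckle) swelling
and task P detects palmar-thenar hypertrophy, two surface signs used in
traditional hand inspection as proxies for myocardial-infarction risk.
The architecture has three parts.

**Shared backbone.** A residual trunk (18-layer-style basic blocks) is
tapped after each of its four stages, producing a feature pyramid
f(1)..f(4) with non-increasing spatial size.  Both tasks read the same
pyramid — the hard-parameter-sharing backbone carries everything that is
common to the two symptoms (palm boundary, skin texture, illumination).

**Task-specific attention branches.** Per task, one attention module per
pyramid level, cascaded.  Each module has two halves.  The first builds a
bounded soft mask

    f′(i) = T(G(f(i)))                      (first module)
    f′(i) = T(G(f(i) ⊕ down(f_m(i−1))))     (subsequent modules)

where ⊕ is channel concatenation, G is 3×3 conv + BN + ReLU, T is 1×1
conv + BN + sigmoid, and `down` is 2×2 average pooling that brings the
previous module's output to the current level's resolution.  The second
half applies the mask with a residual identity,

    f_m(i) = (1 + f′(i)) ⊙ f_IIM(i),

the "+1" preventing the cascade from attenuating features through repeated
multiplication by sub-unit masks.  The branch ends in a 1×1 convolution to
one score map per class followed by global average pooling and softmax.

**Information-interaction module (IIM).** At every level the two branches
exchange masks.  Treating its own task as main information and the other
task as weighted reference information,

    f_IIM_M(i) = T₁ₓ₁(f′_M(i) ⊕ λ₁·f′_P(i))
    f_IIM_P(i) = T₁ₓ₁(f′_P(i) ⊕ λ₂·f′_M(i))

where each T₁ₓ₁ is an independent 1×1 conv + BN halving the concatenated
channel count back to the level width.  Defaults λ₁ = 0.2, λ₂ = 0.4 (the
best-performing weighting reported for this design).  With λ = 0 the
reference half carries zeros and the module degenerates to a per-branch
1×1 — exactly the `no_iim` ablation variant, which the test-suite verifies
by weight surgery to 1e-5.

### Printed-formula ambiguities and how they were resolved

The source formulation of this architecture contains three internal
inconsistencies that any implementation must resolve; the choices here are:

- The masked-output formula is implemented as `(1 + f′(i)) ⊙ f_IIM(i)`,
  reading the sigmoid-bounded first-half output as the attention mask and
  "+1" as the residual identity.  (An alternative reading with an extra
  convolution on the mask cannot be excluded from the prose.)
- The interaction formula is implemented cross-branch (`f′_M ⊕ λ₁·f′_P`),
  as the main/reference description requires, rather than the literal
  self-concatenation its equation typography suggests.
- The IIM consumes the *first-half* outputs f′ of both branches and feeds
  the second half — the only acyclic wiring consistent with the two-part
  module split.
- The two IIM directions use separate 1×1 parameters (sharing is unstated).

## Loss and optimization

Each task contributes a binary cross-entropy on its positive-class softmax
probability (probabilities clamped at 1e-7).  The two losses are combined
with homoscedastic-uncertainty weighting,

    L_total = 1/(2σ_h²)·L_h + 1/(2σ_k²)·L_k + log σ_h² + log σ_k²

(σ_h for task P, σ_k for task M), parameterized as η = log σ² so the
scalars are unconstrained.  The log-term coefficient is kept exactly as
printed (no extra ½).  Note a structural consequence: once both task
losses are near zero the optimum pushes η → −∞, so the total validation
loss keeps falling late in training and best-checkpoint selection favors
late epochs; per-task losses and accuracies are recorded per epoch so this
is visible in the history.  The η scalars are stored in float64 — their
closed-form optimum η* = log(L/2) is asserted against numeric minimization
to 1e-4, which float32 granularity cannot resolve.

Optimization is minibatch Adam with l0 = 0.01, β₁ = 0.9, β₂ = 0.999, no
weight decay, batch size 32, and the five-plateau schedule

    l(s) = l0·[1, 0.5, 0.1, 0.01, 0.001]  on  [0,100], (100,150],
           (150,250], (250,400], (400,500]

with s counting epochs (the breakpoints align with the 500-epoch budget,
not with iteration counts at batch size 32) and the final multiplier held
beyond s = 500.  Model selection keeps the epoch with the minimum total
loss *on the validation set*.

## Preprocessing

Landmarks are four scalars per image: column coordinates X1 > X2 (thumb
boundary / opposite palm edge) and row coordinates Y1 > Y2, giving
ΔX = X1−X2, ΔY = Y1−Y2 and the per-record patch side
P_size = ⌈max(ΔX, ΔY)⌉ (rounded up so the palm is never cropped).  A
dataset-level side is the coverage-quantile (default 1.0) of the P_size
distribution, optionally capped by a hard limit — the clinical default is
460 px, chosen because most palms in a 1200-px capture frame fall under
that size.  The square crop is centred on the landmark bounding-box
midpoint (the only centre expressible from four scalars), out-of-frame
pixels are zero-filled (background carries no signal), and the patch is
bilinearly resized to the network input side (460 for the full preset, 64
for the small test preset).

## Synthetic data

The generator renders what the preprocessing and model need and nothing
more: an elliptical palm on a darker background, landmark extents drawn
from ΔX ~ N(423, 16.26²), ΔY ~ N(439, 27.15²) scaled from the 1200-px
reference frame to the configured image side, and class-conditional
lesions — soft-edged super-Gaussian plateau discs that *brighten* palm
tissue by `lesion_contrast` (default 0.5 on a [0,1] intensity scale)
against pixel noise of sd `noise_sd` (default 0.1).  Task M's lesion is
placed uniformly on the upper quarter band of the palm (the knuckle line),
task P's on the lower-lateral third toward the thumb boundary (the thenar
bulge); the two regions are disjoint by construction and the configuration
is rejected if `lesion_radius` could make them overlap.  Ground-truth
masks record each lesion's half-maximum support.  Class proportions
default to the four-combination balance observed clinically
(537:530:522:570 for (0,0),(0,1),(1,0),(1,1)); a configurable contaminant
fraction carries exclusion flags at the observed criterion frequencies
(peeling 122 : scar 98 : not-unfolded 35).

Two generator choices are load-bearing and deliberate.  Per-record global
brightness (skin tone ±0.08, background ±0.04) varies *more* than the
image-wide mean shift a single lesion causes, so neither task is solvable
from global statistics — each branch must use its own region, which is
what makes branch specialization and localization testable.  And lesions
brighten rather than darken: a ReLU network represents dark regions by
absent activation, which a class-activation map cannot display.

What the generator does **not** emulate: real skin texture, fingers,
illumination gradients, pose or perspective variation, camera noise
statistics, or any correlation between the two symptoms beyond their label
frequencies.  Tests passing on this data therefore demonstrate that the
architecture, training loop and attribution machinery behave as designed —
not that the model reaches any particular accuracy on clinical palm
photographs.

## Grad-CAM and localization scoring

Grad-CAM weights each channel of a branch-specific target layer by the
spatial mean of the class-score gradient and shows the rectified weighted
sum, upsampled and max-normalized.  The target layer defaults to the
deepest attention-module output whose feature grid is at least 4×4 on a
side.  At the full 460-px preset this is the final attention module (a
15×15 grid).  At the 64-px test preset the final module is 2×2 — there
every cell's receptive field covers the whole image and a per-level probe
shows the map carries no usable position information (own-lesion scores
sit below chance at level 4 while levels 2–3 localize well), so the
default backs off to level 3 (4×4).  The level is overridable per call.

Localization against a ground-truth mask is scored threshold-free as
mean(heat inside mask) / (mean inside + mean outside): 0.5 is chance, 1.0
is perfect concentration.  A mean-contrast ratio was chosen over IoU
because CAM heatmaps are soft.

## Ablation variants

`osn` — backbone plus per-task heads only (no branches, no IIM);
`am_subset(S)` — any non-empty subset of the four attention levels, with
bilinear interpolation and a 1×1 channel-matching convolution aligning
non-adjacent levels in the cascade; `no_iim` — cross-links replaced by a
per-branch 1×1+BN on the branch's own mask; `single_task_m`/`_p` — one
branch, no IIM.  The 15-combination attention grid (4 One-AM, 6 Two-AM,
4 Three-AM, the full Four-AM) is enumerated by `am_subset_grid()`.

## Numerical core

No deep-learning framework is used: the network runs on a small
reverse-mode autodiff engine (`palmdx.autograd`) over float32 NumPy
arrays — conv2d via im2col with an explicit col2im adjoint, batch-norm
composed from differentiable primitives with running statistics for
deterministic evaluation, separable bilinear resizing as two matrix
multiplications, and an Adam implementation.  Sigmoid outputs are clamped
to (1e-12, 1−1e-7) so attention masks stay in the open unit interval even
under saturating pre-activations.  Gradients are retained on every graph
node, which is what lets Grad-CAM read d(score)/d(feature map) without
hooks.  All randomness flows through seeded `numpy` generators: dataset
seeds fan out to per-record substreams, and one experiment seed controls
initialization and batch order, so same-seed runs are bit-reproducible on
a fixed platform.

## Problem sizes used in the test-suite

The bundled experiments run at the small preset (64-px input, channels
8/16/32/64, one block per stage): parameter recovery trains 30 epochs on
400 records (320/80 split) and requires ≥ 0.90 validation accuracy on both
tasks; the directional ablation compares full/no-IIM/backbone-only medians
over five seeds at 240 records × 12 epochs; localization is scored on the
recovery model's correctly classified positive validation records.  These
sizes are the package's chosen trade-off between statistical resolution
and a test-suite that runs in minutes on one CPU; the qualitative
orderings they check (full ≥ no_iim, full ≥ osn; own-region localization
above chance and above the other task's region) are scale-robust, the
printed clinical accuracies are not reproducible on synthetic data and are
not targeted.

## Known limitations

- The 64-px preset saturates on the default synthetic difficulty (both
  tasks reach ~100% validation accuracy), so ablation orderings often
  compare ties at the top; harder settings (lower contrast, higher noise)
  spread the variants further but lengthen training.
- Adam at l0 = 0.01 on small batches occasionally produces a transient
  validation-loss spike; best-checkpoint selection rides through it.
- `am_subset` variants interpolate across non-adjacent levels with
  bilinear resizing; the paper-scale behavior of those variants is
  untested here beyond structural checks.
- The uncertainty-weighted total loss is unbounded below in η once task
  losses vanish (see above); for very long runs the η trajectory, not the
  total loss, is the quantity to monitor.
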