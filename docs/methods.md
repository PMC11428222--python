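# Methods

`tdslice` classifies volumetric exams that arrive as ordered stacks of 2-D
grayscale slices (the motivating case is knee MRI read for anterior cruciate
ligament tears).  Two ideas are combined: a *Student-t slice attention*
mechanism that weights slices by position around the informative centre of
the stack, and a *penalty-weight loss* that replaces cross-entropy with an
expected-misclassification-cost objective.  This note records the model, the
choices that were genuinely open, the defaults and their rationale, and the
limits of what the synthetic experiments can show.

## Slice attention

Given per-slice backbone features `M ∈ R^{S×C'×H'×W'}`, each slice is
summarised by global average and global max pooling (`X̄`, `X̃ ∈ R^{S×C'}`).
Two cross-similarity matrices are formed by row-wise softmax,

    S1 = softmax(X̄ X̃ᵀ),   S2 = softmax(X̃ X̄ᵀ),

averaged into `D = (S1 + S2)/2`, and summed over the row index for each
column to give initial per-slice weights `ω` (normalised to the simplex).
The column sum is the only informative reading: rows of a softmax are
stochastic, so the per-row sum is identically 1 and would always produce
uniform weights — the package carries a test asserting exactly this
degeneracy.

A location-shifted, unit-scale Student-t density

    T(x; μ, ν) = Γ((ν+1)/2) / (Γ(ν/2)·√(νπ)) · (1 + (x−μ)²/ν)^(−(ν+1)/2)

is then fitted over the 1-based slice positions: `μ = Σ_s ω_s·s` (the
weighted mean position) and `ν` by moment matching from the weighted
position variance `v = Σ_s ω_s (s−μ)²` via `ν = 2v/(v−1)` (a unit-scale
Student-t has variance ν/(ν−2)).  Because the density has no scale
parameter, the fit needs `v > 1`; degenerate cases (`S = 1`, one-hot ω,
`v ≤ 1`) clamp to `ν_max`, giving a near-point weighting.  `ν` is clamped
to [2.05, 200]: the lower bound keeps the matched variance finite, the
upper bound the density away from a spike.  A configuration option fixes
`ν` verbatim when the user prefers a set tail weight.  The final weights
evaluate the density at positions 1..S and normalise to sum 1.

Two properties follow and are tested: with uniform ω the fit centres at
`(S+1)/2` and weights fall symmetrically and strictly away from the middle;
and the unit-scale density concentrates weight within roughly ±3 slices of
`μ` for any admissible ν, so end slices are suppressed by one to two orders
of magnitude.

**Similarity form.**  `similarity_pair` defaults to raw dot-product logits
(the printed form).  The classifier uses the `cosine` option, which
L2-normalises each slice descriptor before the products: raw dot products
of unnormalised CNN features span hundreds of units, saturating the row
softmax into near-one-hot form, and the position statistics derived from
such spiky matrices wander badly (measured on synthetic exams: |μ − centre|
up to 0.46·S, with end slices occasionally holding 90 % of the weight —
the attention then *amplifies* the end noise it exists to remove).  With
cosine logits the rows stay soft, μ sits within 10⁻³·S of the centre of
coherent feature clusters, and end slices receive ≈ 4 % of the weight.

**Gradient contract.**  The similarity computation runs on the current
features every forward pass, but the fitted scalars (μ, ν) and the weight
vector are treated as non-differentiable constants: gradients flow through
`w ⊗ M` with `w` detached.  The fit is a statistics step, not a learned
layer, and the mechanism adds no trainable parameters (verified by a
parameter-count-equality test across ablation variants).

## Penalty-weight loss

An `n×n` cost matrix `W` holds the cost of predicting class `i` when the
truth is `j`; the diagonal is 1 by convention and off-diagonal entries
default to `|i−j|` (ordinal intent; for `n = 2` this is a single off-diagonal
cost).  The training objective is the expected cost under the softmax output,
written equivalently as

    Σ_i W_ij q_i   with q_i = p_i (i≠j), q_j = 1−p_j      (q-form)
    Σ_i W'_ij p_i  with W'_ii = 0, W'_ij = W_ij + 1       (corrected form)

The two forms coincide exactly whenever `W` has a unit diagonal; the suite
checks the identity on a thousand random instances.  The loss is zero iff
the output is one-hot on the true class, linear in each wrong-class
probability, and its gradient w.r.t. pre-softmax scores is
`p ⊙ (c − cᵀp)` for cost column `c` — checked against central finite
differences.  Asymmetric overrides (e.g. pricing a missed tear above a
false alarm) are exposed; the module default is symmetric.

**Cost balancing in the pipeline.**  A linear expected cost behaves very
differently from cross-entropy under class imbalance: for a constant
prediction p the expected corrected cost is `(1−π)·c_fp·p + π·c_fn·(1−p)`,
which is minimised at the **corner** p = 0 whenever `(1−π)c_fp > πc_fn`.
Cross-entropy's optimal constant prediction is the prior; the linear cost's
is "always majority", and the gradient (∝ p₀p₁) dies exactly there, so a
from-scratch model can be dragged into an inescapable collapse (observed on
some seeds: training loss pinned at 2π, validation AUC decaying).  The
training pipeline therefore defaults to prior-balanced binary costs —
`c_fn/c_fp` set to the training-split class ratio, making constant
predictions cost-neutral so only discriminative directions move the loss.
This is the textbook cost-sensitive remedy and the very use case
(imbalanced tear detection) the penalty weighting is motivated by.  It is
switchable (`penalty_balanced=False` restores symmetric costs) and recorded
in every run's config snapshot.

## Classifier

Slices are replicated to 3 channels, resized to `image_size` (default 64),
and intensity-centred with fixed constants `(x − 0.4)/0.3`.  A small CNN
trunk (registry: `tiny` ≈ 6k parameters, `tiny-wide`, `vgg-mini`) produces
per-slice feature maps; after optional attention re-weighting, each slice is
summarised by its global average *and* global max (`2C'` features), the exam
vector is the coordinatewise maximum over slices, and a dense head produces
softmax probabilities.  Early versions used the average alone; with small
focal lesions the average dilutes the signal by the spatial extent and the
scaled-down protocol could not learn it (train AUC ≈ 0.57 after 10 epochs),
while the avg‖max descriptor learns reliably — so the concatenated form is
the package default.  Max fusion keeps the strongest per-coordinate response
across slices, which is precisely the channel through which noisy end slices
contaminate exam vectors, and the channel the attention weighting cleans.

The fused exam vector passes through a parameter-free layer normalisation
before the head.  This is load-bearing: pooled CNN features are large and
unbounded, so without it ~200 consecutive majority-class steps blow the
logit gap to ≈ 25 within the first epoch when training the expected-cost
loss from scratch; the positive-class probability underflows, the loss
gradient (∝ p₀p₁) vanishes, and the optimiser's stale second moment freezes
the network at "always healthy" (train AUC 0.50).  Cross-entropy resists
via its log barrier; the penalty loss has none, so bounding the logits is
what makes it a genuine drop-in under from-scratch training.

The trunk and head are implemented in a compact NumPy layer library
(im2col convolution, ReLU, 2×2 pooling, layer norm, dense, Adam) with
explicit forward/backward passes; the full model gradient is verified
against finite differences to relative error < 1e-5.

## Evaluation protocol

Confusion counts use strict `score > threshold`.  Accuracy, precision,
recall, specificity and F1 are recomputed from counts; degenerate
denominators return 0 with a logged warning so batch evaluation never
aborts.  The ROC curve is built over all unique score thresholds and the
AUC by trapezoidal integration, which equals the Mann–Whitney pairwise
statistic with ties counted ½ (asserted to 1e-12 against an O(n²) oracle).
Model selection takes the epoch with the best validation AUC (earliest on
ties).  The decision threshold is the accuracy-maximising candidate over
midpoints of adjacent sorted unique validation scores plus ∓∞ sentinels,
ties broken toward the smaller threshold (favouring sensitivity); it is
then frozen and applied to the test split.  Only validation scores ever
reach the threshold search, so test leakage is structurally impossible.

One numerical caveat: the t-density normalisation test integrates over the
full support rather than a fixed ±50 window, because for ν = 2.5 the tails
beyond ±50 still hold ≈ 8e-5 of mass — more than the 1e-6 tolerance the
check uses.

## Synthetic cohorts

The generator emulates the statistical structure the attention mechanism
assumes, not MRI physics.  Per exam: S ~ U{17..61} slices (configurable),
a smooth anatomy background of drifting Gaussian blobs soft-compressed
below ≈ 0.75 intensity, and Gaussian pixel noise (sd 0.08).  The first and
last two slices carry *irrelevant* content: fresh smooth clutter drawn by
the same blob process as the anatomy but decorrelated from the exam's own,
and — with probability 0.2 per end slice — a bright lesion-like distractor
disk that is independent of the label.  End slices are deliberately
*marginally indistinguishable* from interior slices (same intensity offset,
same disk geometry): only position and label-independence make their
content irrelevant, so a max-fusion classifier without a slice filter has
a provable false-positive ceiling, which is exactly the failure mode the
attention weighting removes.  True lesions never touch the end slices.

Positive exams (prevalence 0.2, the approximate ACL-tear fraction of public
knee-MRI cohorts) receive a hard-edged bright disk (radius 6 px) stamped
into a contiguous run of ≈ S/4 slices whose centre is drawn from
Normal(S/2, 1.5) clamped to the interior.  The background compression
matters: without it, overlapping anatomy blobs saturate the grayscale range
and the lesion is statistically invisible even to an oracle probe.  Lesion
contrast is the separability dial — a fixed linear probe's exam-level AUC
rises monotonically with it (tested at three levels) — and the default is
chosen so the reference backbone sits in the middle of the AUC range at the
scaled-down protocol: hard enough that the baseline does not saturate, easy
enough that learning is visible in ten epochs.

Everything derives from a single seed through spawned child generators, so
cohorts, splits and training runs are byte-reproducible.

What passing synthetic tests do **not** show: robustness to scanner
variation, histogram shifts, anatomical confounders, or lesions whose
appearance differs from a bright disk; the phantom makes position the
dominant prior by construction, which is the premise under test, not a
discovery.

## Scaled-down experimental protocol

The directional ablation trains the `tiny` backbone on cohorts of 250 exams
(stratified 8:1:1 → 200/25/25) of 64×64 slices with 8–16 slices per exam
for 10 epochs, Adam, batch size 1 exam, learning rate 3e-3, across the 2×2
grid {attention off/on} × {cross-entropy, penalty loss} with shared seeds
and splits.  These sizes were chosen so a full grid repetition over five
seeds completes in minutes on one CPU core.  The learning rate is the one
deliberate departure from the full-scale convention (1e-5 with large
pretrained backbones): with a small randomly initialised network and fixed
input centring, 1e-3 converges too slowly for the 10-epoch budget and 1e-2
is unstable; 3e-3 converges reliably.  Early stopping triggers when the
epoch-mean training loss falls below ε (default 1e-4; conservative, rarely
active).

Expected outcome shape, not exact values: test AUCs on 25-exam test splits
(≈ 5 positives) are coarse, so single-seed comparisons are noisy and only
multi-seed means are interpreted.

## Known limitations

* The unit-scale Student-t concentrates within a few slices of μ regardless
  of ν; for very long stacks whose informative region is wide, the fitted
  weighting can be narrower than the signal.  A scale parameter would fix
  this but is deliberately out of scope (the fitted form has none).
* The attention statistics adapt to salient features, so a sufficiently
  strong perturbation of an end slice can attract the fit toward it; the
  "end slices matter less" property holds for the weights of the current
  step (the detached-constant semantics), not across refits.
* Backbones are desk-scale; no pretrained weights ship with the package,
  and ImageNet-scale families are out of scope.
* The penalty loss for `n = 2` with symmetric costs is an affine transform
  of `1 − p_true`; its gradient w.r.t. logits vanishes as `p₀p₁ → 0`, i.e.
  near *both* corners, confident-right and confident-wrong alike.  Under
  the one-exam-per-step Adam protocol this matters: Adam's normalised
  steps are nearly magnitude-blind, so the 4:1 majority step-count excess
  drifts the head toward the majority corner, and unlike cross-entropy —
  whose minority-error gradient grows toward O(1) there — the linear cost
  supplies no restoring force.  Prior-balanced costs remove the
  expected-gradient drift and help, but cannot cancel the sign-dynamics;
  the penalty variants consequently show much wider seed-to-seed
  dispersion than their cross-entropy counterparts at the scaled-down
  protocol (individual seeds range roughly 0.4–0.9 test AUC).  Multi-seed
  means remain the only interpretable summary, and conclusions about the
  loss transfer to full-scale settings only where training starts from
  pretrained features at small learning rates, which never enter this
  corner regime.
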