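# Methods

## Problem setting

Pool-based active learning (AL) for patch-level cancer-pathology
classification, in the realistic regime where the unlabeled pool contains
patches that cannot be labelled at all: near-empty or foreign-substance
tiles, out-of-focus regions, air bubbles, tissue folds.  An acquisition
function that chases the most uncertain or highest-loss patches spends a
large share of its labelling budget on exactly these artifacts, because they
sit in the same high-uncertainty region as the genuinely informative clean
patches.  The method implemented here keeps loss-based acquisition but fences
off the extreme upper tail of the predicted-loss axis, where unlabelable
patches concentrate.

## The model

**Joint objective.**  A backbone classifier and a loss prediction module
(LPM) are trained together on

    L = L_target(ŷ, y) + λ · L_loss(l̂, l),

where `L_target` is per-example cross-entropy (mean-reduced) and `L_loss` is
a pairwise margin-ranking hinge.  Within each mini-batch of size B the
examples are paired consecutively into B/2 pairs; for a pair (i, j)

    L_loss = max(0, −𝟙(l_i, l_j) · (l̂_i − l̂_j) + ε),      𝟙 = +1 if l_i > l_j else −1,

averaged over pairs.  The hinge is zero exactly when the predicted losses are
ordered like the true losses with a gap of at least ε.  True losses enter
only as ranking targets (no gradient path); the predicted losses
backpropagate through the LPM into the backbone.  An odd-sized final batch
contributes to the cross-entropy term only.  Defaults: λ = 1, ε = 1,
mean reduction over pairs — the conventions of the learning-loss family.
The ranking indicator is computed on the **true** losses; conditioning it on
the predicted losses would make the hinge a self-referential objective that
any constant-gap prediction satisfies.

**Per-class thresholds.**  During training, the predicted losses of
*correctly* classified examples are recorded per batch and per class.  For
class t, batch-level means are averaged within each epoch and then across
the trailing `z` epochs (default z = 5; the full-scale protocol leaves z
open, and a short trailing window tracks the converged regime without being
dominated by a single epoch's scatter):

    b_final_t = mean over last z epochs of (mean over batches of mean correct l̂).

The acquisition gate is `threshold_t = α_t · b_final_t` with per-class
multipliers α (default 1.0 / 1.1 / 1.0 for benign / dysplasia / malignant,
the reference working point).  Batches with no correct example of a class
are skipped for that class, as are epochs; a class never predicted correctly
in the window has an explicitly *undefined* threshold and its gate is
disabled for that iteration (fail-open), which keeps degenerate early models
from silently discarding an entire class.

The collected quantity is the **predicted** loss l̂, not the true
cross-entropy (a `collect="true"` switch exists).  The gate compares pool
predictions l̂ against the threshold, so both must live on the same scale;
true-loss thresholds (~0.02 after convergence) are meaningless against the
ranking-trained l̂ scale.

**Acquisition.**  At each iteration the trained model predicts
(class, l̂) for every pool patch.  Candidates with l̂ ≥ threshold of their
*predicted* class are excluded; the survivors are ranked by l̂ within each
predicted class and the budget is split into equal per-class quotas
(floor(budget/C), remainder to the classes with the most survivors; a class
that cannot fill its quota hands the shortfall to the globally highest-l̂
remaining survivors).  Ties break by ascending patch id everywhere, making
selections reproducible.  Disabling the gate yields the unfiltered
learning-loss baseline — the identical pipeline minus the threshold — and
with distinct scores the ungated, quota-free ranking is exactly the
argmax of Σ l̂ over size-k subsets.

**Pool update.**  Chosen patches go to the oracle.  Clean patches join the
labeled set; unlabelable ones are discarded from the pool without consuming
a label:

    D_U(i+1) = D_U(i) − p_n − p_l,    D_L(i+1) = D_L(i) + p_l,   |p_n| + |p_l| = budget.

The headline noise metric is the N-ratio: the percentage of the budget spent
on noisy patches, `mean noise count / budget × 100`, aggregated over all
iterations except the first (whose labeled set is the fixed clean seed).

## Architecture choices

The backbone is a four-stage fully connected network (widths 128/64/64/32)
on a fixed feature stem: the patch is average-pooled into an 8×8 grid and
each cell contributes its mean colour and within-cell standard deviation
(local contrast).  The contrast channels retain the high-frequency
information a convolutional front end would see — precisely what
distinguishes defocused or occluded patches from sharp tissue — at a small
fraction of the cost of convolution, which matters because the protocol
retrains from scratch at every iteration on a single CPU.  Parameters are
single precision; gradients are hand-written and verified against finite
differences in the test suite.

The LPM follows the standard design: one tap per backbone stage, each a
fully connected layer to width 128 with ReLU, concatenated and projected to
a scalar.  The final unit passes through a **softplus**.  The ranking hinge
constrains only differences between predicted losses, so a bare linear
output has no scale anchor (empirically it drifts far negative), and the
threshold rule needs a non-negative, loss-like l̂: with b_final ≥ 0,
raising α strictly loosens the gate, which is the semantics the α
sensitivity analysis assumes.

Training: SGD, batch 32, 50 epochs, learning rate 0.001, retrained from
scratch each iteration.  Momentum is 0.5: with this small backbone,
momentum 0.9 at lr 0.001 produced oscillatory late-training collapses in
roughly one fit in ten (final accuracy 0.6–0.8 instead of ≈0.98),
independent of the acquisition strategy; halving the momentum removes them
without touching the prescribed optimizer family, batch size, epoch count or
learning rate.

Comparison strategies: least confidence (ascending max softmax probability),
entropy (descending softmax entropy), BALD (mutual information estimated
from 25 Monte-Carlo-dropout passes, dropout p = 0.5 inserted at the
classifier head of the otherwise dropout-free backbone), core-set k-center
greedy on the penultimate backbone activations (first center = lowest-id
pool point when no labels exist, a fixed stand-in for an arbitrary start),
and uniform random sampling.

## The synthetic corpus

No public corpus matches the one the method was developed on, so the package
ships a generator that emulates its *structure*: three colour/texture
classes (pink / purple / blue-violet bases with class-specific nucleus-like
blob densities) standing in for benign / dysplasia / malignant, and a 5.8%
noisy fraction split between two artifact families:

* **empty/foreign** — near-blank background with a faint mixed stain tint
  and at most a few specks; mean colour saturation is below every clean
  patch's, so the family is detectable in principle;
* **capture artifact** — a pixelwise blend of two classes' textures (capture
  failures straddle tissue boundaries), optionally occluded by bright
  bubble discs or a dark fold band, then defocused by a Gaussian blur;
  high-frequency energy falls below the clean 5th percentile.

Both families are class-ambiguous by construction, which reproduces the
phenomenon the method exploits: unlabelable patches land in the upper tail
of the trained LPM's predicted-loss distribution.  Default scale is 1/10 of
the original protocol — a pool of 3,000 clean + 185 noisy 32×32 patches, a
balanced clean test split of 300, initial labeled set 100, budget 100 per
iteration, 10 iterations, 5 trials — chosen so the full multi-strategy study
runs on a laptop-class CPU; every number is configurable up to the original
scale.  Identical spec + seed reproduces the corpus bit for bit, and the
noise-free twin (`noise_fraction = 0`) shares every clean patch with its
noisy counterpart, enabling matched noisy-vs-clean comparisons.

What the generator does **not** emulate: real tissue morphology, staining
variation, scanner colour profiles, intra-class heterogeneity, label noise
from the oracle, or slide-level correlation between patches.  Passing the
desk-scale study shows the *mechanism* works end to end — thresholds track
the correct-prediction loss scale, the gate removes the upper tail, noise
acquisition drops by a factor of ~2–5 relative to ungated loss acquisition
while accuracy matches the clean-pool run — not that specific full-scale
percentages transfer to any real corpus.

## Numerical and protocol details

* Seeds: a single experiment seed derives per-trial, per-iteration and
  per-component streams through `numpy` SeedSequence spawning; the initial
  labeled set and model initialisations depend only on (seed, trial), never
  on the strategy, so compared strategies start from identical states.
* The initial labeled set is drawn from clean pool patches only, matching
  the protocol's fixed clean first iteration; noise summaries exclude
  iteration 1.
* Images are quantized to 8-bit at generation time, so PNG round-trips are
  lossless and disk-backed corpora reproduce in-memory ones exactly.
* Empty selections (every candidate gated) fall back to the ungated ranking
  with a logged warning rather than stalling the loop.
* A pool smaller than the budget truncates the selection and flags the
  record; totals remain conserved.
* `n_ratio` validates 0 ≤ mean ≤ budget; entropy uses the 0·log 0 = 0
  convention; softmax is computed with the log-sum-exp-stable routine in
  double precision.

## Known limitations

* The desk-scale backbone is not a VGG-16; absolute accuracies and loss
  scales differ from the original full-scale study, and relative orderings
  among the *balanced* baselines (BALD vs entropy vs least confidence) need
  not transfer.  The headline orderings do reproduce: the gated sampler's
  N-ratio falls well below both the unfiltered baseline's and random
  sampling's, while its accuracy matches the matched clean-pool run.
* Thresholds are collected from training-time predicted losses while the
  gate is applied with the final model; the residual scale drift across the
  last epochs is absorbed by α but not modelled.
* The oracle is perfect and instantaneous; oracle label noise is out of
  scope.
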