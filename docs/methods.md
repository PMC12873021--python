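# Methods

## Model

An instance `x ∈ [0,1]^d` (in the EHR setting, binary presence indicators
of diagnoses and medications in one admission) is masked element-wise by
`m = U(sᵀG + ε)` before prediction, where

- `G ∈ [0,1]^{k×d}` is a matrix of *soft feature groups*: row `G_j` gives
  each feature's importance inside candidate phenotype `j`. `G` is stored
  as unconstrained parameters passed through a sigmoid, so the box
  constraint holds by construction rather than by projection.
- `s ∈ ℝ^k` are selection weights produced by a two-layer, bias-free
  network `z = W₂ relu(W₁ x)` followed by either `softmax(z)` (convex
  combination, CC) or `z/‖z‖₁` (restricted affine combination, RAC). CC
  weights live on the simplex; RAC weights satisfy `Σ|s_j| = 1`,
  `|s_j| ≤ 1`, and a negative weight de-selects a group's features.
- `U(w) = max(0, min(1, w))` clamps to the unit interval. `ε` is zero-mean
  Gaussian noise (std `σ`, drawn per mask element) injected only during
  end-to-end training; it pushes mask entries toward {0,1} and lets the
  optimizer explore alternative group combinations. Evaluation always uses
  `ε = 0`, so evaluation-time forwards are pure functions of (input,
  parameters).

The bias-free selector follows the printed selection equations literally;
an all-zero input therefore yields zero logits, which is uniform weights
under CC and a 0/0 under RAC — the RAC selector falls back to uniform
weights `1/k` (the group average) and emits a warning.

Two prediction architectures wrap the grouping module. `FlexGPCMLP` feeds
the masked instance to a one-hidden-layer sigmoid classifier (multi-label
or binary). `FlexGPCTransMLP` masks each visit of a patient sequence with
the *shared* grouping module, encodes the masked sequence with a one-layer
one-head Transformer, and applies a per-position head. Attention is causal
(a visit attends only to itself and earlier visits): the task predicts the
next admission's diagnosis groups, and bidirectional attention would leak
future labels. Position information enters through learned positional
embeddings; both choices are this implementation's, as the architecture
description leaves them open. The per-visit target is the following
admission's label-group multi-hot; the final visit has no target and is
excluded from the prediction loss (the only consistent choice), though it
still contributes to the reconstruction and sparsity terms.

## Objective

    L = L_pred + λ_r · L_recons + λ_m · Σ_{ij} m_ij + λ_g · I(G)

- `L_pred`: binary cross-entropy summed over outputs, averaged over
  instances (computed on logits internally for numerical stability;
  reported values clip probabilities at 1e-7).
- `L_recons = Σ_i ‖X_i − φ(X̂_i)‖₂`, with `φ` a two-layer MLP
  reconstructing the full input from the masked input. The norm is
  unsquared Euclidean per instance (the literal reading of the notation);
  a squared variant would only change the term's scale and curvature.
- `Σ m_ij` is an L1 sparsity penalty on masks.
- `I(G) = −(1/d)Σ Gᵀ log Gᵀ − (1/k)Σ G log G` (natural log, `0·log 0 := 0`)
  is applied to the raw entries, not row-normalized distributions; both
  sums run over the same k·d entries, so `I(G) = (1/d + 1/k)·Σ(−G log G)`.
  It vanishes exactly for binary groups and is maximized at entries `1/e`,
  pushing groups toward crisp memberships.

The canonical objective is the unweighted sum (all λ = 1). The weights
exist because the raw terms scale very differently with `d` and the batch
size; the desk-scale preset uses `λ_r = 0.1`, `λ_m = 1e-3`, `λ_g = 1e-2`,
chosen from a term-magnitude analysis at `d = 100` (the sparsity sum alone
is otherwise ~10⁴ against a prediction loss of ~10¹).

## Training

Phase 1 pre-trains the mask by minimizing `Σ (m_ij − X_ij)²` with respect
to the selector and `G` (both parents of `m` receive gradients), anchoring
masks to the observed records before any label information is used. Phase
2 minimizes the composite objective end-to-end with Adam (batch size 100),
keeping the parameters of the best validation-prediction-loss epoch (early
stopping, patience 10). All randomness — initialization, batch order, mask
noise, splits — flows from one explicit seeded generator; two runs with
the same seed produce bit-identical histories and checkpoint hashes.

Three numerical choices matter and were made after observing a degenerate
attractor on sparse binary inputs (~9% nonzero):

1. **Pre-training is noise-free.** With `ε` active, the expected squared
   loss is minimized by driving *every* pre-clamp value as negative as
   possible — the ~91% zero entries dominate and the noise leaks gradient
   through the clamp — collapsing all masks to zero. Pre-training is a
   fit, not an exploration phase, so `ε = 0` there; noise stays on in
   phase 2, where the prediction loss opposes collapse.
2. **RAC selector starts on its convex face** (`W₂` initialized
   non-negative). With sign-mixed initialization the fastest descent
   direction flips all selection weights negative — a single global move
   that zeroes every mask and from which gradients cannot recover.
   Negative (de-selecting) weights remain fully reachable during training.
3. **Groups start sparse** (`G` entries ≈ 0.05). Inactive features are
   then fitted from the outset and gradient signal comes from active
   features growing their groups, instead of a tug-of-war pulling the
   whole of `G` downward.

Other defaults follow the reference protocol: selector and reconstructor
hidden width `l = 400`, predictor hidden width 200, Transformer dim 200,
`σ = 1`, 80/10/10 split, 5 repetitions. The protocol does not state the
learning rate, epoch counts, or initialization scale; the defaults
(`lr = 1e-3`, 10 pre-training epochs, up to 100 main epochs) are recorded
in `TrainingConfig`. The desk-scale preset (`desk_scale_config`) uses
`k = 10` groups, `lr = 5e-3`, 100 pre-training epochs — the pre-training
loss plateaus by roughly epoch 80–100 at this problem size — and 20 main
epochs, giving minutes-scale CPU experiments.

## Metrics

- **Accuracy@k**: positive labels among the k highest-scoring labels over
  total positives, micro-averaged (summed numerators over summed
  denominators) across instances. Instances with zero positive labels are
  excluded (zero denominator); `k` beyond the label space is truncated
  with a warning. Ties in scores break by ascending label index.
- **AUC**: Mann–Whitney statistic with 0.5 credit for ties (delegated to
  scikit-learn's `roc_auc_score`).
- **RankSim**: both masks are sorted by descending value with ties broken
  by ascending feature index; RankSim is the fraction of rank positions
  occupied by the same feature in both orderings. The deterministic
  tie-break is what makes the quantity well defined for real-valued masks
  and lets exact-duplicate masks score 1 regardless of ties.
- **Stability(i)**: mean RankSim over all *ordered* pairs of the B runs,
  including each run with itself, so identical runs score exactly 1 and
  the diagonal bounds the score below by 1/B. The mean over instances is
  reported alongside per-instance values.

## Verification oracles

The combination schemes' structural claims are checked by enumeration, not
symbolic algebra, because the clamp makes the reachable sets non-linear:

- `reachable` enumerates weight vectors on a grid (default resolution
  0.05) over the simplex (CC), the signed L1 sphere (RAC), or the same
  followed by clamping (CRAC), and reports whether any combination comes
  within an L∞ tolerance (default 0.05) of a target.
- `min_group_count` searches candidate subsets exhaustively in ascending
  size. Reachability is evaluated on the *mask map*, which is always
  clamped; for CC the clamp is a no-op on groups in [0,1]. The worked
  construction (`fig_construction`) uses three binary base groups — two of
  them overlapping — plus the clamped half-difference of the overlapping
  pair; the half (rather than the raw difference) is what the L1
  constraint `Σ|s_j| = 1` actually permits, a normalization subtlety the
  span-style argument for scheme expressiveness glosses over. The family
  needs 4 groups under CC and 3 under RAC.
- `lipschitz_estimate` samples weight vectors uniformly on the L1 sphere
  (Dirichlet magnitudes, random signs) and group-matrix pairs, and
  reports the maximum ratio of mask-output distance to group-stack
  Frobenius distance; the analytic bound is 1.
- `uniform_stability_probe` retrains on leave-one-out cohorts, matches
  group rows across runs by greedy maximum cosine, and measures γ̂ (max
  matched row shift) and β̂ (max mask shift). β̂ is computed with the
  reference model's selection weights applied to both group matrices,
  because the stability argument bounds the mask shift *induced by the
  group shift* at fixed combination weights; the end-to-end shift with
  each run's own selector and the row-matching cost are reported alongside
  so any violation is attributable.

## Synthetic cohorts

`generate_cohort` plants `k_true` sparse soft groups (entries zero with
probability 0.88, else Uniform(0.5, 1)), gives each patient a primary
group (weight ~U(0.55, 0.75)) and a secondary group carrying the remaining
weight — negative with probability `frac_negative_weight`, so planted
masks contain genuine de-selection structure — and draws each visit's
features as Bernoulli(m*) plus a 2% background activation rate. Visit
counts are 1 + Poisson(avg_visits − 1) with a default mean of 2.7 visits
per patient, mirroring the multi-admission structure of real ICU cohorts
at roughly 1/60 scale (default n = 500 patients, d = 100 features, 8
groups, 20 label groups). Next-visit labels come from a fixed random
linear-logistic map of the next visit's planted-mask-filtered features
(~15% positive rate per label group); mortality from a logistic map of the
last visit's. `inject_missingness` zeroes observed entries at rates such
as 0/20/40%; `inject_noise` adds Gaussian input noise at std 0/0.1/0.5.

What the generator does *not* emulate: comorbidity correlations beyond the
planted groups, coding drift across visits, label noise from miscoding,
visit-dependent masks, or the scale of real claims data (thousands of
codes, d ≈ 3000–6000). Passing recovery tests therefore shows the
method's machinery works where its assumptions hold exactly — it does not
certify performance on real EHR data.

## Problem sizes used in checks

Constraint conformance uses 10⁴ random input/parameter draws; the
Lipschitz bound 10⁵ random trials (k ∈ {2,3,4}, d ∈ {3,5}); reachability
nesting 50 random group matrices with k ≤ 3, d ≤ 4. Mask-recovery and
stability experiments use the default cohort (n = 500, d = 100,
k_true = 8, 30% negative-weight patients), the desk-scale preset, 3 seeds
for the variant comparison (RAC vs AVG vs MLPMASK, paired over seeds) and
B = 5 seeded repetitions with and without pre-training for the stability
trend. The leave-one-out stability probe runs on a 60-instance toy block
cohort with shortened schedules.

## Known limitations

- The absolute Stability numbers on the synthetic cohort (~0.2–0.25) are
  far below what saturated, near-binary masks would give: rank-position
  matching over d = 100 real-valued masks is a harsh criterion, and only
  the trend (pre-training improves stability) is asserted.
- The pure-NumPy networks are single-threaded and desk-scale by design;
  there is no GPU path and no hierarchical sequence model.
- `min_group_count` and `reachable` are exhaustive and guarded (candidate
  pools ≤ 6, grids ≤ 10⁷ points); they are verification oracles, not
  tools for large k.
- The RAC degenerate fallback (uniform weights at zero logits) is
  non-differentiable at the switch; it is only reachable for inputs with
  all-zero selector activations.
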