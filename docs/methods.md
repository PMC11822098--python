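# Methods

This note records the model as implemented, the choices that were genuinely
open, and what the synthetic stimulus generator does and does not emulate.

## Task and stimuli

The six Shepard–Hovland–Jenkins problems are two-way classifications of the
8 stimuli spanned by three binary psychological dimensions. The canonical
truth tables are stored once (`stimuli._CATEGORY_A`): Type I is a
one-dimensional rule, Type II the exclusive-or of two dimensions, Types
III–V rule-plus-exception structures (III with a two-bit-distant exception,
IV the linearly separable "at most one odd feature" structure, V with a
one-bit-distant exception) and Type VI parity. A test re-derives the
relevant-dimension counts (1, 2, 3, 3, 3, 3) from the tables by brute force.
Counterbalancing permutes physical dimensions by `permutations[restart mod 6]`.
Trial sequences are per-repetition random permutations of the 8 stimuli;
the sequence depends only on the seed, never on the problem, so the same
restart index sees the same stimulus order in every problem type.

## Perceptual encoding and the stand-in backbone

Each binary feature value owns a seeded 4-dimensional sub-vector ("block"),
emulating a localized stimulus part (legs, antennae, mouth); the clean
encoding of a stimulus is the concatenation of its three blocks (12 units).
Augmentation — the stand-in for image flipping, rotation and shear — applies
a per-sample global gain (±20%), a per-block gain (±20%) and additive
Gaussian jitter (s.d. 0.1), deterministically per seed; the default set is
1,024 augmented samples per stimulus.

The backbone is a frozen, seeded bank of F = 64 rectified linear filters.
Each filter is tuned to one dimension's block (unit-scale weights) with weak
cross-dimension mixing (scale 0.005). The tuning gives the redundancy the
costly-energy principle needs — several filters carry each dimension, so
attention gates can be zeroed without losing an attended feature — and the
small cross-mixing keeps a filter's usefulness tied to its preferred
dimension. The 3-unit sigmoid readout is fine-tuned by Adam on minibatch
cross-entropy (batch 16, up to 1,000 epochs, early stopping with patience 20
on a held-out 20% split) with a small L2 weight decay (3e-3). The decay
matters: without it the logistic readout drives raw activations deep into
sigmoid saturation, and no gradient can flow from the cluster layer back to
the attention gates. A leave-one-stimulus-out variant of the fine-tuning
protocol (`holdout_evaluation`) scores generalization of the readout.

What the generator does *not* emulate: pixel-level rendering, hierarchical
convolutional feature re-use, within-category visual variability beyond the
parametric perturbations, and any asymmetry between physical dimensions
(every dimension is equally discriminable by construction). Passing tests
therefore show that the *algorithmic* structure produces the published
patterns, not that they survive real image statistics.

## Controller

Clusters activate by attention-weighted similarity
`H_j = exp(−c (Σ_i α_i |h_ji − a_i|^r)^{q/r})` with r = 2, q = 1
(Euclidean), compete through a softmax-share inhibition (inverse temperature
t), and contribute a graded readout `H_out = softmax(u·H_comp) ⊙ H_comp`;
association weights map readouts to two category units and a softmax with
scale d yields response probabilities. Recruitment: the first trial always
recruits; afterwards a cluster is recruited when the readout-weighted mean
of per-cluster supports `(w_correct − w_incorrect)/(|w_correct| +
|w_incorrect|)` falls below the threshold τ. A fresh cluster's support (0/0)
is defined as 0, and a duplicate-center guard (on by default; configurable
off) skips recruitment onto an existing center.

The minimized loss is mean binary cross-entropy over the two output units
plus γ·H(α), where H is the Shannon entropy of attention. Minimizing
attention entropy (positive γ) is what drives selectivity; the sign is
exposed in config (`attention_entropy_sign`) for sensitivity analyses. All
gradients are analytic (verified against central finite differences at
1e-5 relative tolerance) and attention is projected back to the
non-negative simplex (clamp, renormalize) after each step.

## Peripheral update (costly energy)

At the start of each trial — after the controller's step — the cluster
readouts of all 8 stimuli are snapshotted (`H_true`). The attention gates g
then take `n_iterations` gradient steps on
`λ · mean((H_true − H_pred)²) + ‖g‖₁`, where `H_pred` is recomputed from the
current g; g is clamped non-negative. The update always uses the entire
stimulus set, not the current trial's stimulus. λ defaults to 1e10: the
double softmax shrinks cluster readouts (and hence reconstruction gradients)
by roughly 1/J² for J clusters, and λ is the only scale that makes the
reconstruction term able to defend needed filters against the unit-scale L1
pull. Only λ's effect is constrained — costly-energy patterns without
behavioral collapse — not its nominal size.

## Model variants

* **M1** (default): controller on task loss; peripheral on the
  costly-energy loss.
* **M3**: as M1 without the L1 term (reconstruction only).
* **M2 / M4**: both modules descend one shared λ-scaled cross-entropy of the
  current trial, with (M2) or without (M4) the L1 term. The per-trial
  procedure is kept identical to M1 — one controller step, then
  `n_iterations` attention steps — with only the objective changed; the
  controller gradient is taken at the pre-update state.

In simulations the shared-loss variants forfeit coordination signatures:
M2 recruits surplus clusters on the easiest problem and its learning curve
is not monotone; M4 never develops the task-graded sparsity pattern (its
gates stay near 1 for every problem type), i.e. it fails the
resource-expenditure signature rather than the behavioral one.

## Numerical choices

* Probabilities are clamped to [1e-12, 1 − 1e-12] before logarithms;
  0·log 0 ≡ 0 in entropies.
* Controller gradients are clipped per parameter group to L2 norm 0.5
  before the learning rate is applied. The cross-entropy's 1/p factor makes
  a single confidently wrong trial otherwise throw attention to a simplex
  vertex, which destabilizes the rule-plus-exception problems late in
  learning. Peripheral gradients are capped element-wise at ±10 for the
  analogous reason (the reconstruction term's curvature under large λ).
  Clipping changes step sizes, never directions.
* The distance's q/r = 1/2 power is non-differentiable at zero distance;
  the subgradient 0 is used there.
* Winner-take-all checks exclude near-ties (gap < 1e-4) by construction.
* Sparsity counts |g| ≤ 1e-3 as zero; this threshold is reported with all
  sparsity numbers.
* Cross-entropy losses use natural logarithms; only the compression score
  uses base-2 logarithms, as `1 + H₂(α)/log₂(1/3)`.

## Default hyperparameters

Selected by the packaged grid search (`scripts/select_defaults.py`) against
the published qualitative record (difficulty ordering, modal cluster counts
2/4/6/6/6/8, attention strategies, sparsity and information-loss orderings);
no fitted values are published for this task family.

| parameter | value | meaning |
|---|---|---|
| c | 2.0 | cluster specificity (receptive-field width) |
| t | 1.0 | competition inverse temperature |
| u | 8.0 | readout concentration (graded; WTA as u → ∞) |
| d | 8.0 | decision scale |
| γ | 0.01 | attention-entropy penalty |
| τ | −0.1 | recruitment threshold on totalSupport |
| lr centers / attention / assoc | 0.02 / 0.15 / 0.3 | controller learning rates |
| λ | 1e10 | reconstruction weight |
| n_iterations | 10 | peripheral steps per trial |
| lr_g | 1e-3 | peripheral learning rate |
| F, cross_scale | 64, 0.005 | backbone size and mixing |

The packaged simulations use 100 restarts × 32 repetitions per problem
(counterbalanced, seeded); analyses use 8-trial blocks (one repetition).
Trial-level scoring defaults to expected error (1 − p_correct); sampled
(argmax) scoring is available by flag.

## Fitting machinery

`fit_to_curves` is a hierarchical (coarse-then-refined) grid search
minimizing the mean squared error between model and target per-repetition
error curves; the refined stage searches midpoints around the coarse optimum
and never returns a worse score. It recovers planted parameters in
self-recovery tests. No human data are bundled; any curves CSV with the
documented schema can be fitted.

## Analyses

Attention compression is `1 + H₂(ᾱ_block)/log₂(1/3)` on the mean attention
within each 8-trial block (0 = uniform, 1 = one-hot). The two-way
repeated-measures ANOVA (problem complexity × learning block, models as
subjects) uses an explicit sum-of-squares decomposition, each effect tested
against its effect-by-subject interaction; it agrees with brute-force
computation to 1e-10 and with an independent implementation. Per-model OLS
slopes (closed form) with a one-sample t-test quantify trends of sparsity
and information loss against the number of relevant dimensions. Information
loss is per-dimension binary cross-entropy of the final peripheral outputs
against the binary feature codings; a before/after-learning reference is
available by flag (the two coincide insofar as pre-learning outputs are
binary, which fine-tuning achieves to within 0.1 per dimension).

## Known limitations

* The backbone is a shallow stand-in; layer-position search across a deep
  hierarchy is represented only by its two-procedure evaluation protocol
  (within-sample and hold-out success), implemented generically.
* The difficulty margin between Types III–V and VI is modest (~0.02 in mean
  error), so orderings are asserted on ≥100-restart populations.
* The shared-loss variants' instability is qualitative and scale-dependent;
  at desk scale M4's failure is the missing resource-expenditure pattern,
  not behavioral collapse.
* Real-participant fitting (per-participant sequences, fMRI correspondence)
  requires data that are not bundled; only the machinery is provided.
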