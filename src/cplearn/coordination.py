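"""Trial-by-trial coordination of controller and peripheral, and experiment drivers.

Model variants:

* ``M1`` (controller-peripheral): the controller takes one gradient step on the
  task loss; the peripheral then optimizes its attention gates against the
  costly-energy objective (cluster-readout reconstruction + L1 sparsity).
* ``M2``: both modules take simultaneous gradient steps on a shared loss of
  lambda-scaled categorization cross-entropy + L1 on g.
* ``M3``: controller-peripheral, but the peripheral objective drops the L1
  penalty (reconstruction only).
* ``M4``: end-to-end — both modules descend the shared lambda-scaled
  cross-entropy with no sparsity pressure.

Recruitment logic is identical across variants.  Per trial the response is
recorded *before* feedback-driven updates; learning curves aggregate the
expected error (1 - p_correct) per 8-trial repetition over restarts, with
counterbalanced dimension mappings cycling across restart indices.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from . import controller as ctrl
from . import peripheral as periph
from .stimuli import (ALL_STIMULI, N_STIMULI, AugmentParams, ProblemType,
                      StimulusEncoder, augmented_dataset, derive_seed,
                      generate_sequence, make_problem, restart_mapping)

VARIANTS = ("M1", "M2", "M3", "M4")
_SHARED_LOSS = {"M2", "M4"}          # simultaneous steps on one objective
_L1_ON = {"M1": True, "M2": True, "M3": False, "M4": False}


def classify_error(p: np.ndarray, label: int, mode: str = "expected") -> float:
    """Probability-of-error bookkeeping for one response.

    ``expected`` scores 1 - p_correct (smooth, restart-efficient);
    ``argmax`` scores 0/1 by the modal response (ties count as errors).
    """
    p = np.asarray(p, dtype=float)
    if mode == "expected":
        return float(1.0 - p[label])
    if mode == "argmax":
        return float(0.0 if p[label] > p[1 - label] else 1.0)
    raise ValueError(f"unknown scoring mode {mode!r}")


@dataclass
class RunResult:
    """One restart's trial-by-trial record."""

    type_id: str
    variant: str
    seed: int
    mapping: tuple[int, ...]
    stim_indices: np.ndarray           # (n_trials,)
    labels: np.ndarray                 # (n_trials,)
    expected_error: np.ndarray         # (n_trials,) 1 - p_correct at response
    correct: np.ndarray                # (n_trials,) argmax correctness
    alpha_traj: np.ndarray             # (n_trials, 3) controller attention
    g_traj: np.ndarray                 # (n_trials, F) peripheral attention
    n_clusters_traj: np.ndarray        # (n_trials,)
    outputs_pre: np.ndarray            # (8, 3) peripheral outputs pre-learning
    outputs_final: np.ndarray          # (8, 3) peripheral outputs post-learning
    final_state: ctrl.ClusterState
    final_g: np.ndarray

    @property
    def n_repetitions(self) -> int:
        return len(self.labels) // N_STIMULI

    @property
    def final_cluster_count(self) -> int:
        return int(self.n_clusters_traj[-1])

    def error_by_repetition(self) -> np.ndarray:
        return self.expected_error.reshape(self.n_repetitions, N_STIMULI).mean(axis=1)


def build_peripheral(master_seed: int,
                     pparams: periph.PeripheralParams,
                     encoder: StimulusEncoder | None = None,
                     n_filters: int = 64,
                     n_augment: int = 1024,
                     aug: AugmentParams | None = None
                     ) -> tuple[StimulusEncoder, periph.PeripheralState]:
    """Construct and fine-tune the shared peripheral for an experiment.

    The encoder/backbone seeds derive from the master seed; the readout is
    fine-tuned once on the augmented stimulus set and shared across restarts
    (each restart resets the attention gates g to one).
    """
    encoder = encoder or StimulusEncoder(seed=derive_seed(master_seed, 101))
    backbone = periph.Backbone(seed=derive_seed(master_seed, 102),
                               n_filters=n_filters, n_inputs=encoder.n_units)
    state = periph.PeripheralState(backbone)
    X, Y = augmented_dataset(encoder, derive_seed(master_seed, 103),
                             n_augment, aug)
    periph.finetune_output_layer(state, X, Y, pparams,
                                 seed=derive_seed(master_seed, 104))
    return encoder, state


@dataclass
class CPModel:
    """A controller-peripheral model instance bound to one restart."""

    variant: str
    cparams: ctrl.ControllerParams
    pparams: periph.PeripheralParams
    peripheral: periph.PeripheralState
    responses: np.ndarray                       # (8, F) cached backbone responses
    clusters: ctrl.ClusterState = field(default_factory=ctrl.ClusterState)

    @classmethod
    def create(cls, variant: str, cparams: ctrl.ControllerParams,
               pparams: periph.PeripheralParams,
               encoder: StimulusEncoder,
               peripheral_template: periph.PeripheralState) -> "CPModel":
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        state = peripheral_template.copy()
        state.attention_g = np.ones(state.backbone.n_filters)
        responses = state.backbone.respond(encoder.encode_all())
        return cls(variant=variant, cparams=cparams, pparams=pparams,
                   peripheral=state, responses=responses)

    def feature_outputs(self) -> np.ndarray:
        """Current peripheral outputs a^in for all 8 clean stimuli."""
        return self.peripheral.forward_filters(self.responses)


def run_trial(model: CPModel, stim_index: int, label: int) -> dict:
    """One learning trial; returns the pre-update response record."""
    a_all = model.feature_outputs()
    a_in = a_all[stim_index]

    if model.clusters.n_clusters > 0:
        p = ctrl.forward(a_in, model.clusters, model.cparams).p
    else:
        p = np.full(2, 0.5)          # no clusters yet: no evidence either way
    record = {
        "p": p,
        "expected_error": classify_error(p, label, "expected"),
        "correct": classify_error(p, label, "argmax") == 0.0,
    }

    model.clusters, recruited = ctrl.maybe_recruit(
        model.clusters, a_in, label, model.cparams)
    record["recruited"] = recruited

    if model.variant in _SHARED_LOSS:
        _shared_loss_step(model, a_in, stim_index, label)
    else:
        model.clusters = ctrl.update_controller(
            model.clusters, a_in, label, model.cparams)
        # snapshot the cluster readouts before this trial's g optimization
        H_true = periph.cluster_readouts(
            model.peripheral, model.responses, model.clusters, model.cparams)
        model.peripheral = periph.update_peripheral(
            model.peripheral, model.responses, H_true, model.clusters,
            model.cparams, model.pparams, include_l1=_L1_ON[model.variant])
    return record


def _shared_loss_step(model: CPModel, a_in: np.ndarray, stim_index: int,
                      label: int) -> None:
    """Both modules descend one shared loss (the non-coordinated variants).

    The loss is the lambda-scaled categorization cross-entropy of the current
    trial (plus L1 on g for the costly-energy variant M2).  The training
    procedure mirrors the coordinated one — a single controller step followed
    by ``n_iterations`` peripheral steps per trial — only the objective
    changes: g now chases the trial-specific task gradient instead of
    preserving the controller's cluster readouts.
    """
    lam = model.pparams.lam
    cp, pp = model.cparams, model.pparams
    y = np.zeros(2)
    y[label] = 1.0
    out = ctrl.forward(a_in, model.clusters, cp)
    grads = ctrl._backprop(a_in, model.clusters, cp, out, y)

    new = model.clusters.copy()
    new.centers -= cp.lr_centers * ctrl.clip_gradient(
        lam * grads["centers"], cp.grad_clip)
    new.assoc -= cp.lr_assoc * ctrl.clip_gradient(
        lam * grads["assoc"], cp.grad_clip)
    new.attention = ctrl.project_attention(
        new.attention - cp.lr_attention * ctrl.clip_gradient(
            lam * grads["attention"], cp.grad_clip))
    model.clusters = new

    # peripheral branch: through a_in = sigmoid(W (x*g) + b), trial stimulus
    x = model.responses[stim_index]
    g = model.peripheral.attention_g
    for _ in range(pp.n_iterations):
        a = model.peripheral.forward_filters(x)
        o = ctrl.forward(a, model.clusters, cp)
        gr = ctrl._backprop(a, model.clusters, cp, o, y)
        g_raw = lam * gr["stimulus"] * a * (1.0 - a)
        g_g = x * (g_raw @ model.peripheral.out_weights)
        if _L1_ON[model.variant]:
            g_g = g_g + pp.l1_weight * np.sign(g)
        if pp.grad_clip > 0:
            g_g = np.clip(g_g, -pp.grad_clip, pp.grad_clip)
        g = np.maximum(g - pp.lr_g * g_g, 0.0)
        model.peripheral.attention_g = g


def run_restart(problem: ProblemType, variant: str, restart_index: int,
                master_seed: int, cparams: ctrl.ControllerParams,
                pparams: periph.PeripheralParams,
                encoder: StimulusEncoder,
                peripheral_template: periph.PeripheralState,
                n_repetitions: int = 32) -> RunResult:
    """One simulated learner: a full trial sequence under one variant."""
    seq_seed = derive_seed(master_seed, 1, restart_index)
    sequence = generate_sequence(problem, seq_seed, n_repetitions)
    model = CPModel.create(variant, cparams, pparams, encoder,
                           peripheral_template)
    outputs_pre = model.feature_outputs()

    n_trials = len(sequence)
    stim_idx = np.array([int(s[0] * 4 + s[1] * 2 + s[2])
                         for s in sequence.stimuli.astype(int)])
    exp_err = np.empty(n_trials)
    correct = np.empty(n_trials, dtype=bool)
    alpha_traj = np.empty((n_trials, 3))
    g_traj = np.empty((n_trials, model.peripheral.backbone.n_filters),
                      dtype=np.float32)
    n_clusters = np.empty(n_trials, dtype=int)

    for trial in range(n_trials):
        rec = run_trial(model, stim_idx[trial], int(sequence.labels[trial]))
        exp_err[trial] = rec["expected_error"]
        correct[trial] = rec["correct"]
        alpha_traj[trial] = model.clusters.attention
        g_traj[trial] = model.peripheral.attention_g
        n_clusters[trial] = model.clusters.n_clusters

    return RunResult(
        type_id=problem.type_id, variant=variant, seed=seq_seed,
        mapping=problem.mapping, stim_indices=stim_idx,
        labels=sequence.labels, expected_error=exp_err, correct=correct,
        alpha_traj=alpha_traj, g_traj=g_traj, n_clusters_traj=n_clusters,
        outputs_pre=outputs_pre, outputs_final=model.feature_outputs(),
        final_state=model.clusters, final_g=model.peripheral.attention_g)


@dataclass
class ExperimentResult:
    """Aggregated restarts for one (type, variant)."""

    type_id: str
    variant: str
    master_seed: int
    runs: list[RunResult]

    @property
    def n_restarts(self) -> int:
        return len(self.runs)

    def learning_curve(self) -> np.ndarray:
        """Mean error probability per repetition over stimuli and restarts."""
        return np.mean([r.error_by_repetition() for r in self.runs], axis=0)

    def cluster_counts(self) -> list[int]:
        return [r.final_cluster_count for r in self.runs]

    def modal_cluster_count(self) -> int:
        return Counter(self.cluster_counts()).most_common(1)[0][0]

    def dominant_attention_counts(self, threshold: float = 0.1) -> list[int]:
        """Per-restart number of end-of-learning attention dimensions >= threshold."""
        return [int((r.alpha_traj[-1] >= threshold).sum()) for r in self.runs]

    def modal_dominant_dimensions(self, threshold: float = 0.1) -> int:
        return Counter(self.dominant_attention_counts(threshold)).most_common(1)[0][0]


def run_experiment(type_id: str, variant: str = "M1", n_restarts: int = 100,
                   n_repetitions: int = 32, master_seed: int = 0,
                   cparams: ctrl.ControllerParams | None = None,
                   pparams: periph.PeripheralParams | None = None,
                   encoder: StimulusEncoder | None = None,
                   peripheral_template: periph.PeripheralState | None = None,
                   n_filters: int = 64, n_augment: int = 1024,
                   aug: AugmentParams | None = None) -> ExperimentResult:
    """Population of independent restarts (analogous to individual learners).

    Restart ``r`` uses the counterbalanced mapping ``permutations[r mod 6]``
    and a sequence seed derived from (master_seed, r); the same master seed
    gives identical stimulus sequences across problem types and variants.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    cparams = cparams or ctrl.ControllerParams()
    pparams = pparams or periph.PeripheralParams()
    if peripheral_template is None:
        encoder, peripheral_template = build_peripheral(
            master_seed, pparams, encoder, n_filters, n_augment, aug)
    assert encoder is not None
    runs = []
    for r in range(n_restarts):
        problem = make_problem(type_id, restart_mapping(r))
        runs.append(run_restart(problem, variant, r, master_seed, cparams,
                                pparams, encoder, peripheral_template,
                                n_repetitions))
    return ExperimentResult(type_id=type_id, variant=variant,
                            master_seed=master_seed, runs=runs)


# ---------------------------------------------------------------------------
# Fitting to learning curves
# ---------------------------------------------------------------------------

def _curve_mse(model_curves: dict[str, np.ndarray],
               target_curves: dict[str, np.ndarray]) -> float:
    errs = []
    for tid, target in target_curves.items():
        m = model_curves[tid]
        n = min(len(m), len(target))
        errs.append(np.mean((m[:n] - np.asarray(target)[:n]) ** 2))
    return float(np.mean(errs))


def _evaluate_point(point: dict, target_curves: dict[str, np.ndarray],
                    master_seed: int, n_restarts: int,
                    n_repetitions: int, base_c: ctrl.ControllerParams,
                    base_p: periph.PeripheralParams) -> float:
    from dataclasses import replace
    ckeys = {f.name for f in ctrl.ControllerParams.__dataclass_fields__.values()}
    pkeys = {f.name for f in
             periph.PeripheralParams.__dataclass_fields__.values()}
    cp = replace(base_c, **{k: v for k, v in point.items() if k in ckeys})
    pp = replace(base_p, **{k: v for k, v in point.items() if k in pkeys})
    encoder, template = build_peripheral(master_seed, pp, n_augment=128)
    curves = {}
    for tid in target_curves:
        res = run_experiment(tid, "M1", n_restarts, n_repetitions,
                             master_seed, cp, pp, encoder=encoder,
                             peripheral_template=template)
        curves[tid] = res.learning_curve()
    return _curve_mse(curves, target_curves)


def fit_to_curves(target_curves: dict[str, np.ndarray],
                  grid: dict[str, list], master_seed: int = 0,
                  n_restarts: int = 10, n_repetitions: int | None = None,
                  refine: bool = True,
                  base_cparams: ctrl.ControllerParams | None = None,
                  base_pparams: periph.PeripheralParams | None = None
                  ) -> tuple[dict, float]:
    """Hierarchical (coarse-then-refined) grid search by learning-curve MSE.

    ``target_curves`` maps problem type to a per-repetition error curve; the
    search minimizes the average MSE between model and target curves.  The
    refinement stage searches midpoints around the coarse optimum and never
    returns a worse score.  Deterministic given grid and master seed.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty hyperparameter grid")
    if n_repetitions is None:
        n_repetitions = max(len(c) for c in target_curves.values())
    base_c = base_cparams or ctrl.ControllerParams()
    base_p = base_pparams or periph.PeripheralParams()

    def search(points: list[dict]) -> tuple[dict, float]:
        best, best_score = None, np.inf
        for point in points:
            score = _evaluate_point(point, target_curves, master_seed,
                                    n_restarts, n_repetitions, base_c, base_p)
            if score < best_score:
                best, best_score = point, score
        return best, best_score

    keys = sorted(grid)
    coarse_points = [dict(zip(keys, combo))
                     for combo in itertools.product(*(grid[k] for k in keys))]
    best, best_score = search(coarse_points)

    if refine:
        refined_axes = {}
        for k in keys:
            values = sorted(set(grid[k]))
            v = best[k]
            neighbors = {v}
            i = values.index(v)
            if i > 0:
                neighbors.add((v + values[i - 1]) / 2)
            if i < len(values) - 1:
                neighbors.add((v + values[i + 1]) / 2)
            refined_axes[k] = sorted(neighbors)
        refined_points = [dict(zip(keys, combo)) for combo in
                          itertools.product(*(refined_axes[k] for k in keys))]
        refined_points = [p for p in refined_points if p != best]
        cand, cand_score = search(refined_points) if refined_points \
            else (None, np.inf)
        if cand_score < best_score:
            best, best_score = cand, cand_score
    return best, best_score
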