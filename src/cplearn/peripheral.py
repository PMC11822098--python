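"""The attention-gated perceptual peripheral, standing in for the ventral stream.

A frozen, seeded filter bank (the backbone) maps continuous stimulus encodings
to F rectified filter responses; per-filter attention gates g (all initialized
at one) multiply those responses before a fine-tuned 3-unit sigmoid readout
produces the psychological feature vector the controller consumes.

During category learning only g is optimized, under the costly-energy
objective: preserve the controller's cluster readouts (reconstruction MSE,
weighted by lambda) while shrinking the L1 norm of g.  The backbone is built
with redundant, dimension-tuned filters so that sparsifying g is possible
without losing attended features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import controller as ctrl
from .stimuli import ALL_STIMULI, N_DIM, StimulusEncoder, AugmentParams, \
    augmented_dataset

EPS = 1e-12


def sigmoid_output(x: np.ndarray) -> np.ndarray:
    """Logistic squashing of raw feature activations into (0, 1)."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def apply_attention(responses: np.ndarray, attention_g: np.ndarray) -> np.ndarray:
    """Filter-wise (Hadamard) attention gating; g broadcasts over batch axes."""
    responses = np.asarray(responses, dtype=float)
    attention_g = np.asarray(attention_g, dtype=float)
    if responses.shape[-1] != attention_g.shape[-1]:
        raise ValueError(
            f"got {responses.shape[-1]} filter responses for "
            f"{attention_g.shape[-1]} attention weights")
    return responses * attention_g


@dataclass
class Backbone:
    """Frozen seeded ReLU filter bank over the stimulus encoding.

    Each filter is preferentially tuned to one psychological dimension's
    encoding block (weights O(1) there) with weak cross-dimension mixing
    (scaled by ``cross_scale``), giving a redundant population code in which
    subsets of filters carry each dimension.
    """

    seed: int = 0
    n_filters: int = 64
    n_inputs: int = 12
    cross_scale: float = 0.005
    weights: np.ndarray = field(init=False, repr=False)
    bias: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.seed)
        block = self.n_inputs // N_DIM
        w = rng.normal(0.0, self.cross_scale,
                       size=(self.n_filters, self.n_inputs))
        preferred = np.arange(self.n_filters) % N_DIM
        for f in range(self.n_filters):
            lo = preferred[f] * block
            w[f, lo:lo + block] = rng.normal(0.0, 1.0, size=block)
        self.weights = w
        self.bias = rng.normal(0.0, 0.1, size=self.n_filters)

    def respond(self, encodings: np.ndarray) -> np.ndarray:
        """Rectified filter responses; frozen during all learning."""
        return np.maximum(np.asarray(encodings, float) @ self.weights.T
                          + self.bias, 0.0)


@dataclass
class PeripheralParams:
    """Hyperparameters of the peripheral.

    lam: weight of the cluster-reconstruction MSE in the costly-energy loss.
    l1_weight: scale of the L1 attention penalty (the printed loss fixes it
        at 1, with lam scaling the reconstruction term).
    n_iterations: gradient steps on g within each trial.
    lr_g: learning rate for g.
    zero_threshold: |g| at or below this counts as a zeroed weight.
    finetune_*: output-layer fine-tuning protocol (Adam, minibatches,
        early stopping on a held-out validation split).
    """

    lam: float = 1e10
    l1_weight: float = 1.0
    n_iterations: int = 10
    lr_g: float = 1e-3
    grad_clip: float = 10.0
    zero_threshold: float = 1e-3
    finetune_lr: float = 3e-3
    finetune_weight_decay: float = 3e-3
    finetune_epochs: int = 1000
    finetune_patience: int = 20
    finetune_batch_size: int = 16
    finetune_val_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class PeripheralState:
    """Backbone + attention gates + fine-tuned readout."""

    backbone: Backbone
    attention_g: np.ndarray = field(default=None)
    out_weights: np.ndarray = field(default=None)   # (3, F)
    out_bias: np.ndarray = field(default=None)      # (3,)

    def __post_init__(self) -> None:
        F = self.backbone.n_filters
        if self.attention_g is None:
            self.attention_g = np.ones(F)
        if self.out_weights is None:
            self.out_weights = np.zeros((N_DIM, F))
        if self.out_bias is None:
            self.out_bias = np.zeros(N_DIM)

    def copy(self) -> "PeripheralState":
        return PeripheralState(self.backbone, self.attention_g.copy(),
                               self.out_weights.copy(), self.out_bias.copy())

    def forward_filters(self, responses: np.ndarray) -> np.ndarray:
        """Feature outputs from (cached) backbone responses."""
        gated = apply_attention(responses, self.attention_g)
        return sigmoid_output(gated @ self.out_weights.T + self.out_bias)

    def forward(self, encodings: np.ndarray) -> np.ndarray:
        """Feature outputs a^in in (0,1)^3 from stimulus encodings."""
        return self.forward_filters(self.backbone.respond(encodings))

    def to_json(self) -> str:
        return json.dumps({
            "backbone_seed": self.backbone.seed,
            "n_filters": self.backbone.n_filters,
            "n_inputs": self.backbone.n_inputs,
            "cross_scale": self.backbone.cross_scale,
            "attention_g": self.attention_g.tolist(),
            "out_weights": self.out_weights.tolist(),
            "out_bias": self.out_bias.tolist(),
        })

    @classmethod
    def from_json(cls, payload: str) -> "PeripheralState":
        d = json.loads(payload)
        bb = Backbone(seed=d["backbone_seed"], n_filters=d["n_filters"],
                      n_inputs=d["n_inputs"], cross_scale=d["cross_scale"])
        return cls(bb, np.array(d["attention_g"], float),
                   np.array(d["out_weights"], float),
                   np.array(d["out_bias"], float))


# ---------------------------------------------------------------------------
# Output-layer fine-tuning (pre category learning)
# ---------------------------------------------------------------------------

def _bce(pred: np.ndarray, target: np.ndarray) -> float:
    p = np.clip(pred, EPS, 1.0 - EPS)
    return float(-np.mean(target * np.log(p) + (1 - target) * np.log(1 - p)))


def finetune_output_layer(state: PeripheralState, samples: np.ndarray,
                          targets: np.ndarray, params: PeripheralParams,
                          seed: int = 0) -> dict:
    """Fit the 3-unit sigmoid readout to binary feature targets.

    Adam on minibatch cross-entropy with an 80/20 train/validation split and
    early stopping (patience ``finetune_patience``); the backbone is frozen
    and attention stays at its initialization.  Returns a small report with
    the best validation loss and whether early stopping converged; weights
    are updated in place to the best-validation snapshot.
    """
    rng = np.random.default_rng(seed)
    n = len(samples)
    perm = rng.permutation(n)
    n_val = max(1, int(round(params.finetune_val_fraction * n))) \
        if params.finetune_epochs > 0 else 0
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    X = state.backbone.respond(samples)
    Xg = apply_attention(X, state.attention_g)
    Y = np.asarray(targets, dtype=float)

    W, b = state.out_weights.copy(), state.out_bias.copy()
    mW = np.zeros_like(W); vW = np.zeros_like(W)
    mb = np.zeros_like(b); vb = np.zeros_like(b)
    beta1, beta2, eps_adam, step = 0.9, 0.999, 1e-8, 0
    best = (np.inf, W.copy(), b.copy())
    patience_left = params.finetune_patience
    history = []

    for epoch in range(params.finetune_epochs):
        order = rng.permutation(train_idx)
        for lo in range(0, len(order), params.finetune_batch_size):
            idx = order[lo:lo + params.finetune_batch_size]
            xb, yb = Xg[idx], Y[idx]
            pred = sigmoid_output(xb @ W.T + b)
            # d(mean BCE)/d(raw) for sigmoid outputs
            g_raw = (pred - yb) / (len(idx) * N_DIM)
            # weight decay keeps the readout out of deep sigmoid saturation,
            # so feature outputs keep a usable gradient during learning
            gW = g_raw.T @ xb + params.finetune_weight_decay * W
            gb = g_raw.sum(axis=0)
            step += 1
            for g_, m_, v_, p_ in ((gW, mW, vW, W), (gb, mb, vb, b)):
                m_ *= beta1; m_ += (1 - beta1) * g_
                v_ *= beta2; v_ += (1 - beta2) * g_ ** 2
                mhat = m_ / (1 - beta1 ** step)
                vhat = v_ / (1 - beta2 ** step)
                p_ -= params.finetune_lr * mhat / (np.sqrt(vhat) + eps_adam)
        val_loss = _bce(sigmoid_output(Xg[val_idx] @ W.T + b), Y[val_idx])
        history.append(val_loss)
        if val_loss < best[0] - 1e-9:
            best = (val_loss, W.copy(), b.copy())
            patience_left = params.finetune_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    if params.finetune_epochs > 0:
        state.out_weights, state.out_bias = best[1], best[2]
    converged = patience_left <= 0 or params.finetune_epochs == 0
    return {"val_loss": best[0] if history else None,
            "n_epochs": len(history), "converged": converged,
            "history": history}


def holdout_evaluation(encoder: StimulusEncoder, backbone: Backbone,
                       params: PeripheralParams, seed: int,
                       n_samples: int = 128,
                       aug: AugmentParams | None = None) -> dict:
    """Leave-one-stimulus-out fine-tuning evaluation.

    For each of the 8 stimuli, fit a fresh output layer on the other stimuli's
    augmented samples and score binary recovery (rounded outputs vs. targets)
    of the held-out clean stimulus.  Deterministic per seed.
    """
    per_stimulus = []
    for held in range(len(ALL_STIMULI)):
        X, Y = augmented_dataset(encoder, seed, n_samples, aug, exclude=held)
        st = PeripheralState(backbone)
        finetune_output_layer(st, X, Y, params, seed=seed + held)
        pred = st.forward(encoder.encode(ALL_STIMULI[held]))
        n_correct = int((np.round(pred) == ALL_STIMULI[held]).sum())
        per_stimulus.append({"stimulus": held, "n_dims_correct": n_correct,
                             "success": n_correct == N_DIM})
    rate = float(np.mean([r["success"] for r in per_stimulus]))
    return {"per_stimulus": per_stimulus, "success_rate": rate}


# ---------------------------------------------------------------------------
# Costly-energy objective (within-trial attention optimization)
# ---------------------------------------------------------------------------

def cluster_readouts(state: PeripheralState, responses: np.ndarray,
                     cluster_state: ctrl.ClusterState,
                     cparams: ctrl.ControllerParams) -> np.ndarray:
    """Graded cluster readouts H^out for every stimulus, (8, J)."""
    a_in = state.forward_filters(responses)
    return ctrl.forward_batch(a_in, cluster_state, cparams)["H_out"]


def peripheral_loss(state: PeripheralState, responses: np.ndarray,
                    H_true: np.ndarray, cluster_state: ctrl.ClusterState,
                    cparams: ctrl.ControllerParams,
                    params: PeripheralParams,
                    include_l1: bool = True) -> float:
    """lam * MSE(snapshot cluster readouts, current readouts) + ||g||_1."""
    if H_true is None:
        raise ValueError("missing cluster-readout snapshot")
    H_pred = cluster_readouts(state, responses, cluster_state, cparams)
    loss = params.lam * float(np.mean((H_true - H_pred) ** 2))
    if include_l1:
        loss += params.l1_weight * float(np.abs(state.attention_g).sum())
    return loss


def attention_gradient(state: PeripheralState, responses: np.ndarray,
                       H_true: np.ndarray, cluster_state: ctrl.ClusterState,
                       cparams: ctrl.ControllerParams,
                       params: PeripheralParams,
                       include_l1: bool = True) -> np.ndarray:
    """Analytic gradient of the costly-energy loss w.r.t. attention_g."""
    gated = apply_attention(responses, state.attention_g)
    raw = gated @ state.out_weights.T + state.out_bias
    a_in = sigmoid_output(raw)
    cache = ctrl.forward_batch(a_in, cluster_state, cparams)
    H_pred = cache["H_out"]
    g_H = 2.0 * params.lam * (H_pred - H_true) / H_true.size
    g_a = ctrl.input_gradient_batch(g_H, cache, cluster_state, cparams)
    g_raw = g_a * a_in * (1.0 - a_in)
    g_gated = g_raw @ state.out_weights
    grad = (responses * g_gated).sum(axis=0)
    if include_l1:
        grad = grad + params.l1_weight * np.sign(state.attention_g)
    return grad


def update_peripheral(state: PeripheralState, responses: np.ndarray,
                      H_true: np.ndarray, cluster_state: ctrl.ClusterState,
                      cparams: ctrl.ControllerParams,
                      params: PeripheralParams,
                      include_l1: bool = True) -> PeripheralState:
    """n_iterations gradient steps on g (clamped non-negative).

    Output-layer weights stay at their fine-tuned values; the update uses the
    entire stimulus set (``responses`` holds all 8 backbone responses) to
    avoid over-fitting to the current trial's stimulus.
    """
    new = state.copy()
    for _ in range(params.n_iterations):
        grad = attention_gradient(new, responses, H_true, cluster_state,
                                  cparams, params, include_l1=include_l1)
        if params.grad_clip > 0:
            # per-filter step cap: keeps the strongly-curved reconstruction
            # term from oscillating without limiting how small lr_g can be
            grad = np.clip(grad, -params.grad_clip, params.grad_clip)
        new.attention_g = np.maximum(new.attention_g - params.lr_g * grad, 0.0)
    return new


# ---------------------------------------------------------------------------
# Measures
# ---------------------------------------------------------------------------

def sparsity(attention_g: np.ndarray, zero_threshold: float = 1e-3) -> float:
    """Fraction of attention weights with magnitude <= zero_threshold."""
    g = np.asarray(attention_g, dtype=float)
    if g.size == 0:
        return 0.0
    return float(np.mean(np.abs(g) <= zero_threshold))


def information_loss(outputs: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Per-dimension binary cross-entropy (natural log) of feature outputs.

    ``reference`` is the binary feature coding (or, under the before/after
    convention, the pre-learning outputs).  Outputs equal to the reference
    give ~0; an uninformative output of 0.5 against a binary reference gives
    ln 2.
    """
    p = np.clip(np.asarray(outputs, dtype=float), EPS, 1.0 - EPS)
    ref = np.asarray(reference, dtype=float)
    return -(ref * np.log(p) + (1.0 - ref) * np.log(1.0 - p))
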