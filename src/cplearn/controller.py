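"""The clustering controller: a differentiable generalization of SUSTAIN.

Clusters are radial-basis memory units in the 3-dimensional psychological
feature space.  A stimulus activates each cluster by attention-weighted
similarity; clusters compete (softmax-share inhibition), contribute a graded
readout to the category units through learned association weights, and a new
cluster is recruited whenever the activation-weighted "support" of the current
clustering for the correct response falls below a threshold.  All parameters
(cluster centers, dimensional attention, association weights) are updated by
gradient descent on a cross-entropy loss with an attention-entropy
regularizer; gradients here are analytic and are checked against finite
differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

EPS = 1e-12
N_OUTPUT = 2


@dataclass
class ControllerParams:
    """Hyperparameters of the clustering controller.

    c:  cluster specificity (>0); larger c = narrower receptive fields.
    r, q: distance/similarity exponents (r=2, q=1 gives Euclidean distance).
    t:  inverse temperature of the cluster competition softmax.
    u:  decision concentration of the graded readout; u -> inf recovers
        winner-take-all.
    d:  response-scaling of the category softmax.
    gamma: weight of the attention-entropy regularizer. With
        attention_entropy_sign = +1 (default) a positive gamma *penalizes*
        entropy, driving attention toward task-relevant dimensions.
    recruit_threshold: recruit a new cluster when totalSupport falls below
        this value (in [-1, 1]).
    lr_*: per-parameter-group learning rates.
    """

    c: float = 2.0
    r: float = 2.0
    q: float = 1.0
    t: float = 1.0
    u: float = 8.0
    d: float = 8.0
    gamma: float = 0.01
    attention_entropy_sign: float = 1.0
    recruit_threshold: float = -0.1
    lr_centers: float = 0.02
    lr_attention: float = 0.15
    lr_assoc: float = 0.3
    grad_clip: float = 0.5
    duplicate_center_guard: bool = True

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("c must be > 0")
        if self.r < 1:
            raise ValueError("r must be >= 1")
        if self.q <= 0:
            raise ValueError("q must be > 0")


@dataclass
class ClusterState:
    """The controller's entire learnable state.

    centers: (J, 3) cluster centers h_j.
    assoc:   (2, J) association weights w_kj from cluster j to output unit k,
             initialized at zero for each recruited cluster.
    attention: (3,) non-negative dimensional attention summing to one.
    """

    centers: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3), dtype=float))
    assoc: np.ndarray = field(
        default_factory=lambda: np.empty((N_OUTPUT, 0), dtype=float))
    attention: np.ndarray = field(
        default_factory=lambda: np.full(3, 1.0 / 3.0))

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]

    def copy(self) -> "ClusterState":
        return ClusterState(self.centers.copy(), self.assoc.copy(),
                            self.attention.copy())

    def to_json(self) -> str:
        return json.dumps({
            "centers": self.centers.tolist(),
            "assoc": self.assoc.tolist(),
            "attention": self.attention.tolist(),
        })

    @classmethod
    def from_json(cls, payload: str) -> "ClusterState":
        d = json.loads(payload)
        return cls(np.array(d["centers"], dtype=float).reshape(-1, 3),
                   np.array(d["assoc"], dtype=float).reshape(N_OUTPUT, -1),
                   np.array(d["attention"], dtype=float))


@dataclass
class ControllerOutput:
    """Forward-pass activations, kept for backprop and recruitment."""

    H_act: np.ndarray      # (J,) similarity activations, in (0, 1]
    s_comp: np.ndarray     # (J,) competition softmax shares
    H_comp: np.ndarray     # (J,) post-competition activations
    s_read: np.ndarray     # (J,) readout softmax shares
    H_out: np.ndarray      # (J,) graded readout
    C_out: np.ndarray      # (2,) output-unit activations
    p: np.ndarray          # (2,) response probabilities


def _softmax(x: np.ndarray) -> np.ndarray:
    z = np.exp(x - np.max(x))
    return z / z.sum()


def cluster_activation(stimulus: np.ndarray, state: ClusterState,
                       params: ControllerParams) -> np.ndarray:
    """H_j = exp(-c (sum_i alpha_i |h_ji - a_i|^r)^(q/r)) for every cluster."""
    if state.n_clusters == 0:
        raise ValueError("no clusters recruited yet")
    diff = np.abs(state.centers - np.asarray(stimulus, dtype=float))
    dist = (state.attention * diff ** params.r).sum(axis=1)
    return np.exp(-params.c * np.maximum(dist, 0.0) ** (params.q / params.r))


def compete(H_act: np.ndarray, t: float) -> tuple[np.ndarray, np.ndarray]:
    """Lateral inhibition: each cluster keeps its softmax share of itself.

    Returns (shares, inhibited activations); outputs never exceed inputs and
    the activation ordering is preserved.
    """
    s = _softmax(t * np.asarray(H_act, dtype=float))
    return s, s * H_act


def readout(H_comp: np.ndarray, u: float) -> tuple[np.ndarray, np.ndarray]:
    """Graded readout; for very large u only the winner retains output."""
    s = _softmax(u * np.asarray(H_comp, dtype=float))
    return s, s * H_comp


def output_activation(H_out: np.ndarray, assoc: np.ndarray) -> np.ndarray:
    """C_k = sum_j w_kj H_j^out."""
    if assoc.shape[1] != len(H_out):
        raise ValueError(
            f"association weights have {assoc.shape[1]} columns for "
            f"{len(H_out)} clusters")
    return assoc @ H_out


def response_probability(C_out: np.ndarray, d: float) -> np.ndarray:
    """p_k = softmax(d * C)_k."""
    return _softmax(d * np.asarray(C_out, dtype=float))


def forward(stimulus: np.ndarray, state: ClusterState,
            params: ControllerParams) -> ControllerOutput:
    H_act = cluster_activation(stimulus, state, params)
    s_comp, H_comp = compete(H_act, params.t)
    s_read, H_out = readout(H_comp, params.u)
    C_out = output_activation(H_out, state.assoc)
    p = response_probability(C_out, params.d)
    return ControllerOutput(H_act, s_comp, H_comp, s_read, H_out, C_out, p)


# ---------------------------------------------------------------------------
# Recruitment
# ---------------------------------------------------------------------------

def cluster_support(assoc: np.ndarray, label: int) -> np.ndarray:
    """Per-cluster support for the correct response, in [-1, 1].

    support_i = (w_correct - w_incorrect) / (|w_correct| + |w_incorrect|),
    with the 0/0 case (a fresh, zero-weight cluster) defined as 0 so that new
    clusters neither support nor oppose a response.
    """
    w_correct = assoc[label]
    w_incorrect = assoc[1 - label]
    denom = np.abs(w_correct) + np.abs(w_incorrect)
    out = np.zeros_like(denom)
    nz = denom > 0
    out[nz] = (w_correct[nz] - w_incorrect[nz]) / denom[nz]
    return out


def total_support(supports: np.ndarray, H_out: np.ndarray) -> float:
    """Readout-weighted mean of per-cluster supports, in [-1, 1]."""
    supports = np.asarray(supports, dtype=float)
    H_out = np.asarray(H_out, dtype=float)
    if supports.shape != H_out.shape:
        raise ValueError("supports and H_out must have equal length")
    total = H_out.sum()
    if total <= 0:
        raise ValueError("total readout activation must be positive")
    return float((supports * H_out).sum() / total)


def maybe_recruit(state: ClusterState, stimulus: np.ndarray, label: int,
                  params: ControllerParams) -> tuple[ClusterState, bool]:
    """Recruit a new cluster centered on the stimulus when support is lacking.

    Learning always begins by recruiting on the first trial; afterwards a
    cluster is added whenever totalSupport < recruit_threshold.  The optional
    duplicate-center guard skips recruitment when a cluster already sits
    exactly on the stimulus.
    """
    stimulus = np.asarray(stimulus, dtype=float)
    if state.n_clusters == 0:
        recruit = True
    else:
        out = forward(stimulus, state, params)
        supports = cluster_support(state.assoc, label)
        recruit = total_support(supports, out.H_out) < params.recruit_threshold
    if recruit and params.duplicate_center_guard and state.n_clusters > 0:
        if np.any(np.all(state.centers == stimulus, axis=1)):
            recruit = False
    if not recruit:
        return state, False
    new = state.copy()
    new.centers = np.vstack([new.centers, stimulus[None, :]])
    new.assoc = np.hstack([new.assoc, np.zeros((N_OUTPUT, 1))])
    return new, True


# ---------------------------------------------------------------------------
# Loss and gradients
# ---------------------------------------------------------------------------

def attention_entropy(alpha: np.ndarray) -> float:
    """Shannon entropy (nats) with the 0 log 0 = 0 convention."""
    a = np.clip(np.asarray(alpha, dtype=float), EPS, None)
    return float(-(alpha * np.log(a)).sum())


def controller_loss(p: np.ndarray, y: np.ndarray, alpha: np.ndarray,
                    params: ControllerParams) -> float:
    """Mean binary cross-entropy over output units + entropy regularizer."""
    pc = np.clip(p, EPS, 1.0 - EPS)
    ce = -np.mean(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc))
    reg = params.attention_entropy_sign * params.gamma * attention_entropy(alpha)
    return float(ce + reg)


def _backprop(stimulus: np.ndarray, state: ClusterState,
              params: ControllerParams, out: ControllerOutput,
              y: np.ndarray) -> dict[str, np.ndarray]:
    """Analytic gradients of the task cross-entropy through the forward pass.

    Returns gradients w.r.t. centers, attention (task term only; the entropy
    regularizer is added by the caller), association weights, and the stimulus
    input (needed by the shared-loss model variants).
    """
    stimulus = np.asarray(stimulus, dtype=float)
    p = np.clip(out.p, EPS, 1.0 - EPS)
    K = len(p)
    # dL/dp for mean BCE over output units
    dL_dp = -(y / p - (1.0 - y) / (1.0 - p)) / K
    # through p = softmax(d * C)
    inner = (dL_dp * out.p).sum()
    g_C = params.d * out.p * (dL_dp - inner)
    # C = W @ H_out
    g_W = np.outer(g_C, out.H_out)
    g_Hout = state.assoc.T @ g_C
    # H_out = s_read * H_comp, s_read = softmax(u * H_comp)
    phi = g_Hout * out.H_comp * out.s_read
    g_Hcomp = out.s_read * g_Hout + params.u * (phi - out.s_read * phi.sum())
    # H_comp = s_comp * H_act, s_comp = softmax(t * H_act)
    psi = g_Hcomp * out.H_act * out.s_comp
    g_Hact = out.s_comp * g_Hcomp + params.t * (psi - out.s_comp * psi.sum())
    # H_act = exp(-c * dist^(q/r))
    diff = state.centers - stimulus          # (J, 3)
    adiff = np.abs(diff)
    dist = (state.attention * adiff ** params.r).sum(axis=1)
    g_D = -params.c * out.H_act * g_Hact
    expo = params.q / params.r
    # d(dist^expo)/d(dist); non-differentiable at 0 -> subgradient 0
    safe = dist > 1e-30
    dpow = np.zeros_like(dist)
    dpow[safe] = expo * dist[safe] ** (expo - 1.0)
    g_dist = g_D * dpow
    # dist_j = sum_i alpha_i |h_ji - a_i|^r
    g_alpha = (g_dist[:, None] * adiff ** params.r).sum(axis=0)
    ddist_dh = (state.attention[None, :] * params.r
                * adiff ** (params.r - 1.0) * np.sign(diff))
    g_centers = g_dist[:, None] * ddist_dh
    g_stimulus = -(g_dist[:, None] * ddist_dh).sum(axis=0)
    return {"centers": g_centers, "attention": g_alpha, "assoc": g_W,
            "stimulus": g_stimulus}


def loss_gradients(stimulus: np.ndarray, state: ClusterState,
                   params: ControllerParams, y: np.ndarray,
                   include_entropy: bool = True) -> dict[str, np.ndarray]:
    """Gradients of the full controller loss at the current state."""
    out = forward(stimulus, state, params)
    grads = _backprop(stimulus, state, params, out, y)
    if include_entropy and params.gamma != 0.0:
        a = np.clip(state.attention, EPS, None)
        # d/da of sign*gamma*H(a), H(a) = -sum a log a
        grads["attention"] = grads["attention"] - (
            params.attention_entropy_sign * params.gamma * (np.log(a) + 1.0))
    return grads


def project_attention(alpha: np.ndarray) -> np.ndarray:
    """Clamp negatives to zero and renormalize to the simplex."""
    a = np.maximum(np.asarray(alpha, dtype=float), 0.0)
    total = a.sum()
    if total <= 0:
        return np.full_like(a, 1.0 / len(a))
    return a / total


def clip_gradient(grad: np.ndarray, max_norm: float) -> np.ndarray:
    """Rescale a parameter-group gradient to at most ``max_norm`` (L2).

    Guards the cross-entropy's unbounded 1/p factor on confidently wrong
    trials, which otherwise throws attention to a simplex vertex in a single
    step; direction is preserved.  max_norm <= 0 disables clipping.
    """
    if max_norm <= 0:
        return grad
    norm = float(np.linalg.norm(grad))
    if norm > max_norm:
        return grad * (max_norm / norm)
    return grad


def update_controller(state: ClusterState, stimulus: np.ndarray, label: int,
                      params: ControllerParams) -> ClusterState:
    """One gradient step on the controller loss, then attention projection."""
    y = np.zeros(N_OUTPUT)
    y[label] = 1.0
    grads = loss_gradients(stimulus, state, params, y)
    new = state.copy()
    clip = params.grad_clip
    new.centers -= params.lr_centers * clip_gradient(grads["centers"], clip)
    new.assoc -= params.lr_assoc * clip_gradient(grads["assoc"], clip)
    new.attention = project_attention(
        new.attention
        - params.lr_attention * clip_gradient(grads["attention"], clip))
    return new


# ---------------------------------------------------------------------------
# Batched forward / input-gradient (used by the peripheral's objective)
# ---------------------------------------------------------------------------

def forward_batch(stimuli: np.ndarray, state: ClusterState,
                  params: ControllerParams) -> dict[str, np.ndarray]:
    """Vectorized forward pass over a batch of stimuli; rows are stimuli."""
    if state.n_clusters == 0:
        raise ValueError("no clusters recruited yet")
    stimuli = np.atleast_2d(np.asarray(stimuli, dtype=float))  # (B, 3)
    diff = state.centers[None, :, :] - stimuli[:, None, :]     # (B, J, 3)
    adiff = np.abs(diff)
    dist = (state.attention[None, None, :] * adiff ** params.r).sum(axis=2)
    H_act = np.exp(-params.c * np.maximum(dist, 0.0) ** (params.q / params.r))

    def _sm(x):
        z = np.exp(x - x.max(axis=1, keepdims=True))
        return z / z.sum(axis=1, keepdims=True)

    s_comp = _sm(params.t * H_act)
    H_comp = s_comp * H_act
    s_read = _sm(params.u * H_comp)
    H_out = s_read * H_comp
    return {"stimuli": stimuli, "diff": diff, "adiff": adiff, "dist": dist,
            "H_act": H_act, "s_comp": s_comp, "H_comp": H_comp,
            "s_read": s_read, "H_out": H_out}


def input_gradient_batch(g_Hout: np.ndarray, cache: dict[str, np.ndarray],
                         state: ClusterState,
                         params: ControllerParams) -> np.ndarray:
    """d(loss)/d(stimulus) for a batch, given upstream d(loss)/d(H_out).

    Mirrors the scalar backprop in :func:`_backprop`; equality of the two
    paths is asserted in the test suite.
    """
    s_read, H_comp = cache["s_read"], cache["H_comp"]
    s_comp, H_act = cache["s_comp"], cache["H_act"]
    phi = g_Hout * H_comp * s_read
    g_Hcomp = s_read * g_Hout + params.u * (
        phi - s_read * phi.sum(axis=1, keepdims=True))
    psi = g_Hcomp * H_act * s_comp
    g_Hact = s_comp * g_Hcomp + params.t * (
        psi - s_comp * psi.sum(axis=1, keepdims=True))
    g_D = -params.c * H_act * g_Hact
    expo = params.q / params.r
    dist = cache["dist"]
    dpow = np.zeros_like(dist)
    safe = dist > 1e-30
    dpow[safe] = expo * dist[safe] ** (expo - 1.0)
    g_dist = g_D * dpow                                        # (B, J)
    ddist_dh = (state.attention[None, None, :] * params.r
                * cache["adiff"] ** (params.r - 1.0) * np.sign(cache["diff"]))
    return -(g_dist[:, :, None] * ddist_dh).sum(axis=1)        # (B, 3)


# ---------------------------------------------------------------------------
# Compression
# ---------------------------------------------------------------------------

def compression(alpha: np.ndarray) -> float:
    """Normalized-entropy attention compression: 1 + H2(alpha)/log2(1/3).

    0 for uniform attention, 1 for one-hot attention; the model analog of
    neural compression in vmPFC.
    """
    alpha = np.asarray(alpha, dtype=float)
    a = np.clip(alpha, EPS, None)
    entropy = float(-(alpha * np.log2(a)).sum())
    return 1.0 + entropy / np.log2(1.0 / 3.0)
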