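"""Shepard-Hovland-Jenkins category structures, trial sequences and stimulus encodings.

The six classic two-category problems are defined over the 8 stimuli spanned by
three binary psychological dimensions (e.g. thick/thin legs, thick/thin
antennae, pincer/shovel mouths).  Type I is solvable from one dimension,
Type II is the exclusive-or of two dimensions, Types III-V are
rule-plus-exception structures and Type VI requires memorizing every stimulus.

Stimuli are also given a continuous perceptual encoding: a seeded,
block-structured embedding of the three binary features, with a parameterized
augmentation generator standing in for image-level flip/rotate/shear
perturbations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_DIM = 3
N_STIMULI = 8

#: All 8 feature vectors in lexicographic order; row index == binary code.
ALL_STIMULI: np.ndarray = np.array(
    list(itertools.product((0, 1), repeat=N_DIM)), dtype=float
)

TYPE_IDS = ("I", "II", "III", "IV", "V", "VI")

# Canonical category-A membership per problem type, keyed by the stimulus'
# binary code (d0*4 + d1*2 + d2). Single source of truth for the six
# structures; a test re-derives the relevant-dimension counts from these rows.
_CATEGORY_A: dict[str, frozenset[int]] = {
    "I": frozenset({0b000, 0b001, 0b010, 0b011}),        # d0 alone
    "II": frozenset({0b000, 0b001, 0b110, 0b111}),       # XOR(d0, d1)
    "III": frozenset({0b000, 0b001, 0b010, 0b101}),      # rule d0 + far exception
    "IV": frozenset({0b000, 0b001, 0b010, 0b100}),       # at most one odd feature
    "V": frozenset({0b000, 0b001, 0b010, 0b111}),        # rule d0 + near exception
    "VI": frozenset({0b000, 0b011, 0b101, 0b110}),       # parity
}

#: Number of dimensions required for perfect classification.
N_RELEVANT = {"I": 1, "II": 2, "III": 3, "IV": 3, "V": 3, "VI": 3}

_CANONICAL_RELEVANT = {
    "I": (0,),
    "II": (0, 1),
    "III": (0, 1, 2),
    "IV": (0, 1, 2),
    "V": (0, 1, 2),
    "VI": (0, 1, 2),
}

#: The 6 permutations of (0,1,2) in a fixed order, used for counterbalancing.
DIMENSION_PERMUTATIONS: tuple[tuple[int, ...], ...] = tuple(
    itertools.permutations(range(N_DIM))
)


def _code(stimulus: np.ndarray) -> int:
    s = np.asarray(stimulus, dtype=int)
    return int(s[0] * 4 + s[1] * 2 + s[2])


@dataclass(frozen=True)
class ProblemType:
    """One of the six category structures, with dimensions permuted.

    ``labels[i]`` is the category (0 = A, 1 = B) of the stimulus whose
    *physical* feature vector is ``ALL_STIMULI[i]``.  ``mapping`` sends
    logical (canonical) dimension ``j`` to physical dimension ``mapping[j]``.
    """

    type_id: str
    mapping: tuple[int, ...]
    labels: tuple[int, ...]
    relevant_dims: tuple[int, ...]

    @property
    def n_relevant_dims(self) -> int:
        return len(self.relevant_dims)

    def label_of(self, stimulus: np.ndarray) -> int:
        return self.labels[_code(stimulus)]

    def to_frame(self) -> pd.DataFrame:
        """Export as an 8-row table (three feature columns + label)."""
        df = pd.DataFrame(ALL_STIMULI.astype(int), columns=["d0", "d1", "d2"])
        df["label"] = ["A" if l == 0 else "B" for l in self.labels]
        return df


def make_problem(type_id: str, mapping: tuple[int, ...] = (0, 1, 2)) -> ProblemType:
    """Build a Shepard problem with logical dimensions permuted by ``mapping``.

    A physical stimulus ``s`` is labeled by looking up the canonical table at
    the logical vector ``(s[mapping[0]], s[mapping[1]], s[mapping[2]])``.
    """
    if type_id not in _CATEGORY_A:
        raise ValueError(f"unknown problem type {type_id!r}; expected one of {TYPE_IDS}")
    mapping = tuple(int(m) for m in mapping)
    if sorted(mapping) != [0, 1, 2]:
        raise ValueError(f"mapping must be a permutation of (0, 1, 2), got {mapping}")
    cat_a = _CATEGORY_A[type_id]
    labels = []
    for s in ALL_STIMULI.astype(int):
        logical = tuple(s[m] for m in mapping)
        labels.append(0 if _code(np.array(logical)) in cat_a else 1)
    relevant = tuple(sorted(mapping[j] for j in _CANONICAL_RELEVANT[type_id]))
    return ProblemType(type_id=type_id, mapping=mapping, labels=tuple(labels),
                       relevant_dims=relevant)


@dataclass(frozen=True)
class TrialSequence:
    """Ordered (stimulus, label) trials: ``n_repetitions`` shuffled blocks of 8."""

    stimuli: np.ndarray          # (n_trials, 3) feature vectors
    labels: np.ndarray           # (n_trials,) ints in {0, 1}
    seed: int
    n_repetitions: int
    mapping: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.labels)


def generate_sequence(problem: ProblemType, seed: int,
                      n_repetitions: int = 32) -> TrialSequence:
    """Per-repetition random permutations of the 8 stimuli.

    The stimulus order depends only on ``seed`` (never on the problem), so the
    same seed yields the same sequence across problem types, matching the
    counterbalanced simulation protocol.
    """
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    rng = np.random.default_rng(seed)
    order = np.concatenate(
        [rng.permutation(N_STIMULI) for _ in range(n_repetitions)]
    )
    stimuli = ALL_STIMULI[order]
    labels = np.array([problem.labels[i] for i in order], dtype=int)
    return TrialSequence(stimuli=stimuli, labels=labels, seed=int(seed),
                         n_repetitions=int(n_repetitions), mapping=problem.mapping)


# ---------------------------------------------------------------------------
# Perceptual encodings and augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentParams:
    """Abstract stand-ins for image-level flip/rotate/shear perturbations.

    gain_range: per-sample multiplicative jitter, drawn from U(1-g, 1+g)
        (global contrast/size change).
    block_gain_range: per-dimension-block multiplicative jitter (a geometric
        distortion affects stimulus parts unevenly).
    jitter_sd: additive Gaussian noise s.d. per encoding unit.
    """

    gain_range: float = 0.2
    block_gain_range: float = 0.2
    jitter_sd: float = 0.1


@dataclass
class StimulusEncoder:
    """Seeded deterministic embedding of feature vectors into R^(3*block_size).

    Each binary dimension value owns a dense random sub-vector ("block"),
    emulating a localized stimulus part (legs, antennae, mouth); the clean
    encoding of a stimulus is the concatenation of its three blocks.
    """

    seed: int = 0
    block_size: int = 4
    _blocks: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.seed)
        # _blocks[dim, value] is the block vector for feature `dim` == `value`
        self._blocks = rng.normal(0.0, 1.0, size=(N_DIM, 2, self.block_size))

    @property
    def n_units(self) -> int:
        return N_DIM * self.block_size

    def encode(self, stimulus: np.ndarray) -> np.ndarray:
        s = np.asarray(stimulus, dtype=int)
        return np.concatenate([self._blocks[i, s[i]] for i in range(N_DIM)])

    def encode_all(self) -> np.ndarray:
        """Clean encodings of all 8 stimuli, shape (8, n_units)."""
        return np.stack([self.encode(s) for s in ALL_STIMULI])

    def augment(self, stimulus: np.ndarray, seed: int, n_samples: int,
                params: AugmentParams | None = None) -> np.ndarray:
        """``n_samples`` seeded perturbed encodings of one stimulus.

        Deterministic given (stimulus, seed); with all-zero noise parameters
        the samples are identical copies of the clean encoding.
        """
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        params = params or AugmentParams()
        clean = self.encode(stimulus)
        rng = np.random.default_rng([int(seed), _code(stimulus)])
        gains = rng.uniform(1.0 - params.gain_range, 1.0 + params.gain_range,
                            size=(n_samples, 1))
        block_gains = rng.uniform(1.0 - params.block_gain_range,
                                  1.0 + params.block_gain_range,
                                  size=(n_samples, N_DIM))
        block_gains = np.repeat(block_gains, self.block_size, axis=1)
        noise = rng.normal(0.0, 1.0, size=(n_samples, self.n_units))
        return clean[None, :] * gains * block_gains + params.jitter_sd * noise


def augment(stimulus: np.ndarray, seed: int, n_samples: int = 1024,
            params: AugmentParams | None = None,
            encoder: StimulusEncoder | None = None) -> np.ndarray:
    """Module-level convenience wrapper around :meth:`StimulusEncoder.augment`."""
    encoder = encoder or StimulusEncoder()
    return encoder.augment(stimulus, seed, n_samples, params)


def augmented_dataset(encoder: StimulusEncoder, seed: int,
                      n_samples_per_stimulus: int = 1024,
                      params: AugmentParams | None = None,
                      exclude: int | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Augmented samples for all stimuli (optionally holding one out).

    Returns (encodings, binary targets); targets are the clean feature vectors.
    """
    xs, ys = [], []
    for idx, s in enumerate(ALL_STIMULI):
        if exclude is not None and idx == exclude:
            continue
        xs.append(encoder.augment(s, seed, n_samples_per_stimulus, params))
        ys.append(np.tile(s, (n_samples_per_stimulus, 1)))
    return np.concatenate(xs), np.concatenate(ys)


# ---------------------------------------------------------------------------
# Seed derivation
# ---------------------------------------------------------------------------

def derive_seed(master_seed: int, *path: int) -> int:
    """Hierarchical seed splitting: experiment -> restart -> component.

    Uses numpy's SeedSequence so every sub-experiment is independently
    reproducible from (master_seed, path) alone. The result fits in 31 bits.
    """
    ss = np.random.SeedSequence([int(master_seed), *[int(p) for p in path]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def restart_mapping(restart_index: int) -> tuple[int, ...]:
    """Counterbalanced feature-to-task mapping: cycle the 6 permutations."""
    return DIMENSION_PERMUTATIONS[restart_index % len(DIMENSION_PERMUTATIONS)]
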