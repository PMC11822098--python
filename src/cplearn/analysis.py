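"""Block-wise analyses linking model quantities to their neural counterparts.

Compression of controller attention (the vmPFC analog), sparsity of peripheral
attention and per-dimension information loss (the LOC analogs), plus the
statistical machinery applied to simulated model populations: a within-model
two-way repeated-measures ANOVA with explicit sum-of-squares decomposition,
and per-model OLS slopes tested against zero with a one-sample t-test.

A block is one repetition: eight consecutive trials containing each stimulus
exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .controller import compression
from .coordination import ExperimentResult, RunResult
from .peripheral import information_loss, sparsity
from .stimuli import ALL_STIMULI, N_STIMULI, ProblemType


def block_mean_attention(run: RunResult) -> np.ndarray:
    """Per-block (8-trial) mean controller attention, (n_blocks, 3)."""
    n_blocks = run.n_repetitions
    return run.alpha_traj.reshape(n_blocks, N_STIMULI, -1).mean(axis=1)


def compression_trace(run: RunResult) -> np.ndarray:
    """Block-wise attention compression scores, each in [0, 1]."""
    return np.array([compression(a) for a in block_mean_attention(run)])


def sparsity_trace(run: RunResult, zero_threshold: float = 1e-3) -> np.ndarray:
    """Block-wise fraction of zeroed peripheral attention weights."""
    n_blocks = run.n_repetitions
    g_blocks = np.asarray(run.g_traj, dtype=float).reshape(
        n_blocks, N_STIMULI, -1)[:, -1, :]       # state at end of each block
    return np.array([sparsity(g, zero_threshold) for g in g_blocks])


def info_loss_by_dimension(run: RunResult, problem: ProblemType,
                           reference: str = "binary") -> pd.DataFrame:
    """Per-dimension information loss on the 8 clean stimuli, relevance-tagged.

    ``reference='binary'`` scores the post-learning peripheral outputs against
    the experimenter-defined binary codings; ``reference='pre_learning'``
    scores them against the fine-tuned pre-learning outputs (the two coincide
    insofar as pre-learning outputs are binary).
    """
    if reference == "binary":
        ref = ALL_STIMULI
    elif reference == "pre_learning":
        ref = run.outputs_pre
    else:
        raise ValueError(f"unknown reference {reference!r}")
    loss = information_loss(run.outputs_final, ref)     # (8, 3)
    rows = []
    for dim in range(3):
        rows.append({
            "dim": dim,
            "relevant": dim in problem.relevant_dims,
            "info_loss": float(loss[:, dim].mean()),
        })
    return pd.DataFrame(rows)


@dataclass
class BlockSummary:
    """Tidy per-(model, type, block) analysis rows."""

    frame: pd.DataFrame

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def summarize_blocks(experiments: list[ExperimentResult],
                     zero_threshold: float = 1e-3) -> BlockSummary:
    """One row per model x type x block with compression and sparsity."""
    rows = []
    for exp in experiments:
        for model_id, run in enumerate(exp.runs):
            comp = compression_trace(run)
            spar = sparsity_trace(run, zero_threshold)
            for block in range(run.n_repetitions):
                rows.append({
                    "model_id": model_id,
                    "type": exp.type_id,
                    "variant": exp.variant,
                    "block": block,
                    "compression": comp[block],
                    "sparsity": spar[block],
                })
    return BlockSummary(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Repeated-measures two-way ANOVA (explicit sum-of-squares decomposition)
# ---------------------------------------------------------------------------

def rm_anova_two_way(data: np.ndarray) -> dict[str, dict[str, float]]:
    """Two-way fully-within ANOVA on ``data[subject, factor_a, factor_b]``.

    One observation per cell.  Each effect is tested against its own
    effect-by-subject interaction, the standard repeated-measures error term.
    Returns F, p and degrees of freedom for the two main effects ("a", "b")
    and their interaction ("axb").
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("data must be (subjects, levels_a, levels_b)")
    S, A, B = data.shape
    grand = data.mean()
    m_s = data.mean(axis=(1, 2))
    m_a = data.mean(axis=(0, 2))
    m_b = data.mean(axis=(0, 1))
    m_sa = data.mean(axis=2)
    m_sb = data.mean(axis=1)
    m_ab = data.mean(axis=0)

    ss_a = S * B * ((m_a - grand) ** 2).sum()
    ss_b = S * A * ((m_b - grand) ** 2).sum()
    ss_ab = S * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_as = B * ((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum()
    ss_bs = A * ((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum()
    resid = (data - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
             + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :]
             - grand)
    ss_abs = (resid ** 2).sum()

    def effect(ss, df, ss_err, df_err):
        ms, ms_err = ss / df, ss_err / df_err
        f = ms / ms_err if ms_err > 0 else np.inf
        return {"F": float(f), "p": float(stats.f.sf(f, df, df_err)),
                "df1": df, "df2": df_err, "ss": float(ss),
                "ss_error": float(ss_err)}

    return {
        "a": effect(ss_a, A - 1, ss_as, (A - 1) * (S - 1)),
        "b": effect(ss_b, B - 1, ss_bs, (B - 1) * (S - 1)),
        "axb": effect(ss_ab, (A - 1) * (B - 1), ss_abs,
                      (A - 1) * (B - 1) * (S - 1)),
    }


def compression_anova(summary: BlockSummary,
                      value: str = "compression") -> dict:
    """ANOVA of a block summary with factors problem complexity and block.

    Requires a balanced design: every model_id present for every type and
    block.  Factor "a" is problem complexity (type), "b" is learning block.
    """
    df = summary.frame
    types = sorted(df["type"].unique(), key=lambda t: len(t))
    models = sorted(df["model_id"].unique())
    blocks = sorted(df["block"].unique())
    pivot = df.pivot_table(index="model_id", columns=["type", "block"],
                           values=value, aggfunc="mean")
    expected = len(types) * len(blocks)
    if pivot.isna().any().any() or pivot.shape != (len(models), expected):
        raise ValueError("unbalanced design: every model must be run on "
                         "every type and block")
    data = np.empty((len(models), len(types), len(blocks)))
    for ai, t in enumerate(types):
        for bi, b in enumerate(blocks):
            data[:, ai, bi] = pivot[(t, b)].to_numpy()
    out = rm_anova_two_way(data)
    return {"complexity": out["a"], "block": out["b"],
            "interaction": out["axb"], "types": types, "n_models": len(models)}


# ---------------------------------------------------------------------------
# Per-model regression slopes
# ---------------------------------------------------------------------------

def ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Ordinary least-squares slope of y on x (covariance / variance)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx = ((x - x.mean()) ** 2).sum()
    if vx == 0:
        raise ValueError("degenerate predictor: no variance")
    return float(((x - x.mean()) * (y - y.mean())).sum() / vx)


def slope_test(values: pd.DataFrame, predictor: str,
               dependent: str, model_col: str = "model_id") -> dict:
    """Per-model OLS slopes + one-sample t-test of the slopes against zero.

    ``values`` holds one row per (model, predictor level).  When every slope
    is identical the t statistic is undefined and flagged as such.
    """
    levels = values[predictor].nunique()
    if levels < 2:
        raise ValueError("need at least 2 predictor levels")
    slopes = []
    for _, sub in values.groupby(model_col):
        slopes.append(ols_slope(sub[predictor].to_numpy(),
                                sub[dependent].to_numpy()))
    slopes = np.array(slopes)
    if np.allclose(slopes.std(ddof=1) if len(slopes) > 1 else 0.0, 0.0):
        t, p = (np.nan, np.nan) if not np.allclose(slopes, 0.0) else (np.nan, np.nan)
        return {"slopes": slopes, "mean_slope": float(slopes.mean()),
                "t": float("nan"), "p": float("nan"), "defined": False}
    t, p = stats.ttest_1samp(slopes, 0.0)
    return {"slopes": slopes, "mean_slope": float(slopes.mean()),
            "t": float(t), "p": float(p), "defined": True}


def sparsity_by_relevance(experiments: list[ExperimentResult],
                          zero_threshold: float = 1e-3) -> pd.DataFrame:
    """Final-block sparsity per model with the task's relevant-dimension count."""
    from .stimuli import N_RELEVANT
    rows = []
    for exp in experiments:
        for model_id, run in enumerate(exp.runs):
            rows.append({
                "model_id": model_id,
                "type": exp.type_id,
                "n_relevant": N_RELEVANT[exp.type_id],
                "sparsity": sparsity(run.final_g, zero_threshold),
            })
    return pd.DataFrame(rows)


def info_loss_by_relevance(experiments: list[ExperimentResult],
                           reference: str = "binary") -> pd.DataFrame:
    """Mean information loss per model and type, with relevant-dim count."""
    from .stimuli import N_RELEVANT, make_problem, restart_mapping
    rows = []
    for exp in experiments:
        for model_id, run in enumerate(exp.runs):
            problem = make_problem(exp.type_id, run.mapping)
            df = info_loss_by_dimension(run, problem, reference)
            rows.append({
                "model_id": model_id,
                "type": exp.type_id,
                "n_relevant": N_RELEVANT[exp.type_id],
                "info_loss": float(df["info_loss"].mean()),
                "info_loss_relevant": float(
                    df.loc[df.relevant, "info_loss"].mean()),
                "info_loss_irrelevant": float(
                    df.loc[~df.relevant, "info_loss"].mean())
                if (~df.relevant).any() else float("nan"),
            })
    return pd.DataFrame(rows)
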