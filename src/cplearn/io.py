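"""Readers/writers for artifact files and run logging.

Learning curves, attention trajectories and analysis tables travel as CSV;
model states and statistics reports as JSON.  Every file operation surfaces
the offending path on failure, and curve files are validated on read.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .coordination import ExperimentResult

logger = logging.getLogger("cplearn")

CURVE_COLUMNS = ["type", "variant", "repetition", "error_probability",
                 "n_restarts"]


def setup_logging(level: int = logging.INFO) -> None:
    """Console logging; INFO reports per-repetition error and cluster counts,
    DEBUG additionally dumps attention vectors."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.setLevel(level)
    if not logger.handlers:
        logger.addHandler(handler)


def curves_frame(results: list[ExperimentResult]) -> pd.DataFrame:
    """Tidy learning-curve table: one row per (type, variant, repetition)."""
    if not results:
        raise ValueError("no experiment results to export")
    rows = []
    for res in results:
        curve = res.learning_curve()
        for rep, err in enumerate(curve):
            rows.append({"type": res.type_id, "variant": res.variant,
                         "repetition": rep, "error_probability": float(err),
                         "n_restarts": res.n_restarts})
    return pd.DataFrame(rows, columns=CURVE_COLUMNS)


def write_curves(results: list[ExperimentResult], path: str | Path) -> None:
    try:
        curves_frame(results).to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"failed to write curves to {path}: {exc}") from exc


def read_curves(path: str | Path) -> pd.DataFrame:
    """Read a learning-curve CSV, validating the header."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except OSError as exc:
        raise OSError(f"failed to read curves from {path}: {exc}") from exc
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"malformed curves file {path}: missing columns {missing}")
    return df


def curves_to_targets(df: pd.DataFrame) -> dict[str, np.ndarray]:
    """Convert a curves table into the {type: error-by-repetition} form
    consumed by the fitting machinery."""
    targets = {}
    for tid, sub in df.groupby("type"):
        sub = sub.sort_values("repetition")
        targets[str(tid)] = sub["error_probability"].to_numpy()
    return targets


def write_attention_trajectories(results: list[ExperimentResult],
                                 path: str | Path) -> None:
    """Per-trial controller attention as tidy CSV."""
    rows = []
    for res in results:
        for model_id, run in enumerate(res.runs):
            for trial, alpha in enumerate(run.alpha_traj):
                rows.append({"type": res.type_id, "variant": res.variant,
                             "model_id": model_id, "trial": trial,
                             "alpha0": alpha[0], "alpha1": alpha[1],
                             "alpha2": alpha[2]})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_cluster_counts(results: list[ExperimentResult],
                         path: str | Path) -> None:
    payload = {
        res.type_id: {
            "variant": res.variant,
            "counts": res.cluster_counts(),
            "modal": res.modal_cluster_count(),
        }
        for res in results
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_stats_report(report: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(report, indent=2, default=_default))
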