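"""Metrics, statistics and reporting for decoder comparisons.

The headline metric is the coefficient of determination

    R^2 = 1 - SS_res / SS_tot

computed pooled within a fold per output variable; it may be negative for poor
predictors and is never clipped in stored values (flooring at zero is a
display option only).  Model contrasts use paired two-tailed t-tests on
per-fold scores with Benjamini-Hochberg FDR adjustment across the four output
variables; significance at adjusted p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .arm import ArmParameters, JointState, forward_kinematics

__all__ = ["r_squared", "reconstruct_trajectory", "paired_t_fdr",
           "generalization_report", "EvaluationReport"]

THETA_E_RANGE = (-np.pi, 0.0)


def r_squared(truth: np.ndarray, prediction: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (may be negative)."""
    truth = np.asarray(truth, dtype=float).ravel()
    prediction = np.asarray(prediction, dtype=float).ravel()
    if truth.shape != prediction.shape:
        raise ValueError(f"length mismatch: {truth.shape} vs {prediction.shape}")
    if truth.size < 2:
        raise ValueError("need at least two samples")
    ss_tot = float(((truth - truth.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined for constant truth series")
    ss_res = float(((truth - prediction) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def reconstruct_trajectory(angular_velocity: np.ndarray, initial_theta: np.ndarray,
                           arm: ArmParameters = ArmParameters(),
                           dt: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Hand path from decoded angular velocities by trapezoidal integration.

    ``angular_velocity`` is ``[T, 2]`` (shoulder, elbow; rad/s) on a ``dt``
    grid; ``initial_theta`` the ground-truth initial posture.  Elbow angles
    leaving the convention range ``[-pi, 0]`` are clipped and flagged.
    Returns ``(path [T, 2], clipped_mask [T])``.
    """
    w = np.asarray(angular_velocity, dtype=float)
    theta = np.zeros_like(w)
    theta[0] = initial_theta
    if w.shape[0] > 1:
        increments = 0.5 * (w[1:] + w[:-1]) * dt
        theta[1:] = initial_theta + np.cumsum(increments, axis=0)
    clipped = (theta[:, 1] < THETA_E_RANGE[0]) | (theta[:, 1] > THETA_E_RANGE[1])
    theta[:, 1] = np.clip(theta[:, 1], *THETA_E_RANGE)
    x, y = forward_kinematics(JointState(theta[:, 0], theta[:, 1]), arm)
    return np.stack([x, y], axis=1), clipped


def _paired_t(diff: np.ndarray) -> tuple[float, float, bool]:
    """Paired t on per-fold differences with explicit degenerate handling."""
    diff = np.asarray(diff, dtype=float)
    if diff.size < 2:
        raise ValueError("need at least two paired observations")
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            return 0.0, 1.0, True           # identical models
        sign = float(np.sign(diff.mean()))
        return sign * np.inf, 0.0, True     # constant nonzero difference
    t, p = sstats.ttest_rel(diff, np.zeros_like(diff))
    return float(t), float(p), False


def paired_t_fdr(scores: np.ndarray, model_names: Sequence[str],
                 output_names: Sequence[str], alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise model contrasts with BH-FDR adjustment across outputs.

    ``scores`` has shape ``[models, folds, outputs]`` (paired per fold).  For
    each model pair, raw p-values from paired two-tailed t-tests on the four
    outputs are adjusted together by Benjamini-Hochberg (monotone by
    construction); significance at adjusted p < alpha.
    """
    scores = np.asarray(scores, dtype=float)
    M, F, V = scores.shape
    if M != len(model_names) or V != len(output_names):
        raise ValueError("scores shape inconsistent with names")
    rows = []
    for a in range(M):
        for b in range(a + 1, M):
            raw, metas = [], []
            for v in range(V):
                t, p, degenerate = _paired_t(scores[a, :, v] - scores[b, :, v])
                raw.append(p)
                metas.append((t, degenerate))
            _, adj, _, _ = multipletests(raw, alpha=alpha, method="fdr_bh")
            for v in range(V):
                rows.append({
                    "model_a": model_names[a], "model_b": model_names[b],
                    "output": output_names[v],
                    "mean_diff": float(np.mean(scores[a, :, v] - scores[b, :, v])),
                    "t": metas[v][0], "p_raw": raw[v], "p_adj": float(adj[v]),
                    "significant": bool(adj[v] < alpha),
                    "degenerate": metas[v][1]})
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    """Aggregated R^2 grid with contrasts, exportable as CSV/markdown."""

    r2: pd.DataFrame                         # tidy: target, model, output, fold, r2
    grid: pd.DataFrame                       # mean ± sd with best-model marks
    contrasts: Optional[pd.DataFrame] = None
    meta: dict = field(default_factory=dict)

    def to_markdown(self) -> str:
        return self.grid.to_markdown()

    def save(self, path_prefix: str) -> None:
        self.r2.to_csv(f"{path_prefix}_scores.csv", index=False)
        self.grid.to_csv(f"{path_prefix}_grid.csv")
        if self.contrasts is not None:
            self.contrasts.to_csv(f"{path_prefix}_contrasts.csv", index=False)
        with open(f"{path_prefix}_grid.md", "w") as fh:
            fh.write(self.to_markdown() + "\n")


def generalization_report(runs: pd.DataFrame, alpha: float = 0.05,
                          floor_negative: bool = False) -> EvaluationReport:
    """Aggregate per-(target, model, output, fold) R^2 into the comparison grid.

    ``runs`` must carry a single dataset fingerprint (column ``fingerprint``,
    if present); mixing runs from different datasets is refused.  The grid
    reports mean ± sd over folds and marks the best model per (target, output)
    cell; ``floor_negative`` floors *displayed* means at zero, never the
    stored scores.
    """
    required = {"target", "model", "output", "fold", "r2"}
    missing = required - set(runs.columns)
    if missing:
        raise ValueError(f"runs table missing columns {sorted(missing)}")
    if "fingerprint" in runs.columns and runs["fingerprint"].nunique() > 1:
        raise ValueError("runs come from different dataset fingerprints; refusing to aggregate")

    agg = (runs.groupby(["target", "output", "model"])["r2"]
           .agg(["mean", "std", "count"]).reset_index())
    agg["std"] = agg["std"].fillna(0.0)
    rows = []
    for (target, output), sub in agg.groupby(["target", "output"]):
        best = sub["mean"].idxmax()
        for i, r in sub.iterrows():
            mean = max(r["mean"], 0.0) if floor_negative else r["mean"]
            rows.append({"target": target, "output": output, "model": r["model"],
                         "cell": f"{mean:.3f} ± {r['std']:.3f}" + (" ^" if i == best else ""),
                         "best": i == best})
    grid = (pd.DataFrame(rows)
            .pivot(index=["target", "output"], columns="model", values="cell"))

    contrasts = None
    models = sorted(runs["model"].unique())
    outputs = list(runs["output"].unique())
    folds = sorted(runs["fold"].unique())
    if len(models) > 1 and len(folds) > 1:
        cube = np.full((len(models), len(folds), len(outputs)), np.nan)
        pooled = runs.groupby(["model", "fold", "output"])["r2"].mean()
        for mi, m in enumerate(models):
            for fi, f in enumerate(folds):
                for vi, v in enumerate(outputs):
                    if (m, f, v) in pooled.index:
                        cube[mi, fi, vi] = pooled.loc[(m, f, v)]
        if np.isfinite(cube).all():
            contrasts = paired_t_fdr(cube, models, outputs, alpha)
    return EvaluationReport(runs, grid, contrasts,
                            {"models": models, "outputs": outputs})
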