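"""Linking subgraph expression to behavioral performance.

Reaction-time cost, expression-performance rank correlations, and
regional performance participation scores with permutation nulls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import bh_adjust, spearman
from .characterization import ExpressionSummary

logger = logging.getLogger(__name__)

__all__ = [
    "validate_behavior",
    "reaction_time_cost",
    "expression_performance_correlation",
    "ParticipationScores",
    "participation_score",
    "participation_null_test",
]

BEHAVIOR_COLUMNS = ("subject", "task", "condition", "block", "trial", "rt_ms", "correct")
VALID_CONDITIONS = {"fixation", "low", "high"}


def validate_behavior(behavior: pd.DataFrame) -> pd.DataFrame:
    missing = set(BEHAVIOR_COLUMNS) - set(behavior.columns)
    if missing:
        raise ValueError(f"behavior table missing columns: {sorted(missing)}")
    if (behavior["rt_ms"] <= 0).any():
        raise ValueError("reaction times must be positive")
    bad = set(behavior["condition"].unique()) - VALID_CONDITIONS
    if bad:
        raise ValueError(f"unknown condition label(s): {sorted(bad)}")
    return behavior


def reaction_time_cost(
    behavior: pd.DataFrame, task: str, per_pair: bool = False
) -> pd.Series:
    """Per-subject reaction-time cost (ms) for one task.

    Block means are computed over correct trials only; the cost is the
    mean over high-demand blocks minus the mean over low-demand blocks.
    With ``per_pair=True`` the cost is instead the mean of block-wise
    differences (high block i minus low block i), which coincides with
    the default when block counts match and is defined only when they
    do.  Subjects with no correct trials in a condition are excluded
    (logged).
    """
    behavior = validate_behavior(behavior)
    df = behavior[(behavior["task"] == task)
                  & (behavior["condition"].isin(["low", "high"]))
                  & (behavior["correct"] == 1)]
    block_means = (
        df.groupby(["subject", "condition", "block"])["rt_ms"].mean().reset_index()
    )
    costs = {}
    for subj, part in block_means.groupby("subject"):
        low = part[part["condition"] == "low"].sort_values("block")
        high = part[part["condition"] == "high"].sort_values("block")
        if low.empty or high.empty:
            logger.warning("subject %s has no correct trials in a condition; excluded", subj)
            continue
        if per_pair:
            if len(low) != len(high):
                raise ValueError(
                    f"per-pair cost undefined for subject {subj}: "
                    f"{len(high)} high vs {len(low)} low blocks")
            costs[subj] = float((high["rt_ms"].to_numpy() - low["rt_ms"].to_numpy()).mean())
        else:
            costs[subj] = float(high["rt_ms"].mean() - low["rt_ms"].mean())
    return pd.Series(costs, name="rt_cost_ms").rename_axis("subject")


def expression_performance_correlation(
    summary: ExpressionSummary,
    costs: pd.Series,
    task: str,
    condition: str,
    min_subjects: int = 5,
    with_fdr: bool = False,
) -> pd.DataFrame:
    """Spearman rho between relative expression and RT cost, per subgraph.

    Expression is each subject's mean relative expression over the given
    task/condition blocks.  rho > 0 means greater negative expression
    goes with lower cost.  Raw p-values are reported uncorrected; an
    FDR-adjusted column is added on request.
    """
    means = summary.subject_means(task=task, condition=condition)
    wide = means.pivot(index="subject", columns="subgraph", values="relative")
    common = wide.index.intersection(costs.index)
    if len(common) < min_subjects:
        raise ValueError(f"need >= {min_subjects} subjects, got {len(common)}")
    y = costs.loc[common].to_numpy()
    if np.all(y == y[0]):
        raise ValueError("constant cost vector: rank correlation undefined")
    rows = []
    for k in wide.columns:
        x = wide.loc[common, k].to_numpy()
        if np.all(x == x[0]):  # constant expression: no rank association
            rho, p = np.nan, 1.0
        else:
            rho, p = spearman(x, y)
        rows.append({"subgraph": k, "rho": rho, "p": p})
    out = pd.DataFrame(rows)
    if with_fdr:
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


@dataclass
class ParticipationScores:
    """Regional node strengths and performance participation scores."""

    strengths: np.ndarray  # n_regions x m
    scores: np.ndarray  # n_regions
    rho: np.ndarray  # m
    p: np.ndarray | None = None
    significant: np.ndarray | None = None
    sign_class: np.ndarray | None = None

    def as_frame(self) -> pd.DataFrame:
        data = {"region": np.arange(self.scores.size), "score": self.scores}
        if self.p is not None:
            data["p"] = self.p
            data["significant"] = self.significant
            data["sign_class"] = self.sign_class
        return pd.DataFrame(data)


def _node_strengths(W: np.ndarray, edge_index: np.ndarray, n_regions: int) -> np.ndarray:
    """Node strength per subgraph: sum of a node's edge weights, (N, m)."""
    strengths = np.zeros((n_regions, W.shape[1]))
    np.add.at(strengths, edge_index[:, 0], W)
    np.add.at(strengths, edge_index[:, 1], W)
    return strengths


def participation_score(
    W: np.ndarray, edge_index: np.ndarray, rho_vector, n_regions: int | None = None
) -> ParticipationScores:
    """Rho-weighted sum of node strengths across subgraphs.

    score(i) = sum_k rho_k * strength_k(i).  Positive scores mark
    regions disengaging (via anticorrelated dynamics) with better
    performance; negative scores mark engaging regions.
    """
    W = np.asarray(W, dtype=float)
    rho = np.asarray(rho_vector, dtype=float)
    edge_index = np.asarray(edge_index)
    if rho.shape != (W.shape[1],):
        raise ValueError("rho_vector must have one entry per subgraph")
    if n_regions is None:
        n_regions = int(edge_index.max()) + 1
    strengths = _node_strengths(W, edge_index, n_regions)
    return ParticipationScores(strengths=strengths, scores=strengths @ rho, rho=rho)


def participation_null_test(
    W: np.ndarray,
    edge_index: np.ndarray,
    rho_vector,
    n_perm: int = 10000,
    seed: int | None = None,
    alpha: float = 0.05,
    n_regions: int | None = None,
) -> ParticipationScores:
    """Permutation significance of regional participation scores.

    Each surrogate independently shuffles every subgraph's edge weights
    over node pairs and recomputes all scores.  Regions falling outside
    the two-sided null interval survive Bonferroni correction over
    regions.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    base = participation_score(W, edge_index, rho_vector, n_regions=n_regions)
    W = np.asarray(W, dtype=float)
    edge_index = np.asarray(edge_index)
    n_regions = base.scores.size
    rng = np.random.default_rng(seed)

    # incidence matrix: score = B @ (sum_k rho_k * permuted w_k)
    E = W.shape[0]
    B = np.zeros((n_regions, E))
    B[edge_index[:, 0], np.arange(E)] = 1.0
    B[edge_index[:, 1], np.arange(E)] = 1.0

    ge = np.zeros(n_regions)
    le = np.zeros(n_regions)
    done = 0
    chunk = max(1, min(128, int(2e7 // max(1, E))))
    while done < n_perm:
        size = min(chunk, n_perm - done)
        combined = np.zeros((size, E))
        for k in range(W.shape[1]):
            idx = np.argsort(rng.random((size, E)), axis=1)
            combined += base.rho[k] * W[idx, k]
        scores = combined @ B.T  # size x n_regions
        eps = 1e-9 * np.maximum(1.0, np.abs(base.scores))
        ge += (scores >= (base.scores - eps)[None, :]).sum(axis=0)
        le += (scores <= (base.scores + eps)[None, :]).sum(axis=0)
        done += size
    p_two = 2.0 * np.minimum(ge + 1.0, le + 1.0) / (n_perm + 1.0)
    p_two = np.minimum(p_two, 1.0)
    significant = p_two <= alpha / n_regions
    sign_class = np.where(base.scores >= 0, "disengaged", "engaged")
    return ParticipationScores(strengths=base.strengths, scores=base.scores,
                               rho=base.rho, p=p_two, significant=significant,
                               sign_class=sign_class)
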