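"""Subgraph topology and expression-dynamics characterization.

Relative (positive minus negative channel) expression summaries and
contrasts, core-periphery structure with permutation nulls, system-level
interaction tests, and edge-wise Fisher-Z contrasts.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, fisher_z, spearman
from .networks import ConfigurationMatrix, SystemPartition, edge_list, vectorize_matrix

__all__ = [
    "ExpressionSummary",
    "CorePeripheryResult",
    "ContrastResult",
    "relative_expression",
    "core_periphery_index",
    "system_core_periphery_test",
    "system_interaction_test",
    "expression_hierarchy_correlation",
    "contrast_expression",
    "edge_contrast",
]


# ---------------------------------------------------------------------------
# expression dynamics


@dataclass
class ExpressionSummary:
    """Per-block relative expression of every subgraph.

    ``blocks`` has one row per (subject, task, condition, block,
    subgraph) with positive- and negative-channel coefficients and their
    difference.  ``ranking`` orders subgraphs by decreasing cohort-mean
    relative expression, labelled A, B, C, ...
    """

    blocks: pd.DataFrame
    ranking: pd.DataFrame  # columns: subgraph, label, mean_relative, sign_class
    n_subgraphs: int

    def subject_means(self, **filters) -> pd.DataFrame:
        """Per subject x subgraph mean relative expression, optionally
        restricted by column filters (e.g. task='taskA', condition='low')."""
        df = self.blocks
        for key, value in filters.items():
            df = df[df[key] == value]
        return (
            df.groupby(["subject", "subgraph"], sort=True)["relative"]
            .mean()
            .reset_index()
        )


def _rank_labels(n: int) -> list[str]:
    letters = string.ascii_uppercase
    if n <= len(letters):
        return list(letters[:n])
    return [f"S{i:02d}" for i in range(n)]


def relative_expression(
    H: np.ndarray,
    observation_meta: pd.DataFrame,
    exclude_fixation: bool = True,
) -> ExpressionSummary:
    """Positive minus negative expression per block, ranked cohort-wide.

    Every (subject, task, condition, block) cell must carry both sign
    channels.  Fixation columns are dropped by default: the
    factorization consumes them but characterization is restricted to
    task blocks.
    """
    H = np.asarray(H, dtype=float)
    meta = observation_meta.reset_index(drop=True)
    if H.shape[1] != len(meta):
        raise ValueError("H columns do not match observation metadata")
    m = H.shape[0]

    keys = ["subject", "task", "condition", "block"]
    pos = meta[meta["sign"] == "pos"]
    neg = meta[meta["sign"] == "neg"]
    merged = pos.reset_index().merge(
        neg.reset_index(), on=keys, suffixes=("_pos", "_neg"), how="outer"
    )
    if merged["index_pos"].isna().any() or merged["index_neg"].isna().any():
        raise ValueError("missing sign-channel partner column for some block")

    if exclude_fixation:
        merged = merged[merged["condition"] != "fixation"]

    rows = []
    pos_idx = merged["index_pos"].to_numpy(dtype=int)
    neg_idx = merged["index_neg"].to_numpy(dtype=int)
    for k in range(m):
        hp = H[k, pos_idx]
        hn = H[k, neg_idx]
        part = merged[keys].copy()
        part["subgraph"] = k
        part["positive"] = hp
        part["negative"] = hn
        part["relative"] = hp - hn
        rows.append(part)
    blocks = pd.concat(rows, ignore_index=True)

    subj_means = blocks.groupby(["subject", "subgraph"])["relative"].mean()
    cohort = subj_means.groupby("subgraph").mean().sort_values(ascending=False)
    labels = _rank_labels(m)
    ranking = pd.DataFrame(
        {
            "subgraph": cohort.index.to_numpy(),
            "label": labels,
            "mean_relative": cohort.to_numpy(),
            "sign_class": np.where(cohort.to_numpy() >= 0, "positive", "negative"),
        }
    )
    return ExpressionSummary(blocks=blocks, ranking=ranking, n_subgraphs=m)


# ---------------------------------------------------------------------------
# core-periphery topology


@dataclass
class CorePeripheryResult:
    """Per-system core/periphery scores and the bounded summary index."""

    systems: list
    core: np.ndarray
    periphery: np.ndarray
    index: float
    core_p: np.ndarray | None = None
    periphery_p: np.ndarray | None = None
    core_p_adj: np.ndarray | None = None
    periphery_p_adj: np.ndarray | None = None

    def as_frame(self) -> pd.DataFrame:
        data = {"system": self.systems, "core": self.core, "periphery": self.periphery}
        for name in ("core_p", "periphery_p", "core_p_adj", "periphery_p_adj"):
            value = getattr(self, name)
            if value is not None:
                data[name] = value
        return pd.DataFrame(data)


def _edge_weights(subgraph, edge_index=None):
    w = np.asarray(subgraph, dtype=float)
    if w.ndim == 2 and w.shape[0] == w.shape[1]:
        if not np.allclose(w, w.T):
            raise ValueError("subgraph matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("subgraph matrix must have zero diagonal")
        n = w.shape[0]
        return vectorize_matrix(w), edge_list(n), n
    if w.ndim != 1:
        raise ValueError("subgraph must be a square matrix or an edge vector")
    if edge_index is None:
        raise ValueError("edge vector input requires edge_index")
    edge_index = np.asarray(edge_index)
    return w, edge_index, int(edge_index.max()) + 1


def _system_edge_masks(partition: SystemPartition, edge_index: np.ndarray):
    si = partition.labels[edge_index[:, 0]]
    sj = partition.labels[edge_index[:, 1]]
    systems = partition.systems
    within = {s: (si == s) & (sj == s) for s in systems}
    cross = {s: (si == s) ^ (sj == s) for s in systems}
    return systems, within, cross


def _core_periphery_scores(w, partition, edge_index):
    """Per-system core and periphery scores over ordered node pairs.

    core_s divides the ordered within-system edge sum by |s| exactly as
    defined (not by the pair count); periphery_s is the mean ordered
    edge weight from system s to the rest of the graph.
    """
    n = int(edge_index.max()) + 1
    systems, within, cross = _system_edge_masks(partition, edge_index)
    core = np.empty(len(systems))
    periphery = np.empty(len(systems))
    for idx, s in enumerate(systems):
        size = partition.size(s)
        if size == n:
            raise ValueError(f"system {s} spans every region: no periphery exists")
        core[idx] = 2.0 * w[within[s]].sum() / size
        periphery[idx] = w[cross[s]].sum() / (size * (n - size))
    return systems, core, periphery


def core_periphery_index(subgraph, partition: SystemPartition,
                         edge_index=None) -> CorePeripheryResult:
    """Bounded core-periphery index of one subgraph.

    index = (1/S) * sum_s (core_s - periphery_s) / (core_s + periphery_s),
    with systems whose scores are both zero contributing 0.  The result
    lies in [-1, +1]: +1 when all weight is within systems, -1 when all
    weight is between systems.
    """
    w, edge_index, n = _edge_weights(subgraph, edge_index)
    if np.any(w < 0):
        raise ValueError("subgraph weights must be non-negative")
    if len(partition.systems) < 2:
        raise ValueError("need at least 2 systems")
    if partition.n_regions != n:
        raise ValueError("partition size does not match the subgraph")
    systems, core, periphery = _core_periphery_scores(w, partition, edge_index)
    total = core + periphery
    terms = np.zeros(len(systems))
    nonzero = total > 0
    terms[nonzero] = (core[nonzero] - periphery[nonzero]) / total[nonzero]
    return CorePeripheryResult(systems=systems, core=core, periphery=periphery,
                               index=float(terms.mean()))


def _permute_edges(w: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniformly permute edge weights over node pairs (keeps symmetry and
    the zero diagonal by construction on the edge vector)."""
    return w[rng.permutation(w.size)]


def _permutation_exceedance(
    w: np.ndarray,
    stat_rows: np.ndarray,
    observed: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    chunk: int = 256,
) -> np.ndarray:
    """Count surrogates whose linear edge statistics reach the observed ones.

    ``stat_rows`` is a (n_stats x E) matrix so every statistic is
    ``stat_rows @ w``; surrogates permute the edge vector uniformly.
    """
    exceed = np.zeros(observed.size)
    # float tolerance so exact ties (e.g. constant weights) count as exceedance
    threshold = observed - 1e-9 * np.maximum(1.0, np.abs(observed))
    done = 0
    while done < n_perm:
        size = min(chunk, n_perm - done)
        idx = np.argsort(rng.random((size, w.size)), axis=1)
        perms = w[idx]  # size x E
        stats_perm = perms @ stat_rows.T  # size x n_stats
        exceed += (stats_perm >= threshold[None, :]).sum(axis=0)
        done += size
    return exceed


def system_core_periphery_test(
    subgraph,
    partition: SystemPartition,
    n_perm: int = 10000,
    seed: int | None = None,
    edge_index=None,
    bonferroni_extra: int = 1,
) -> CorePeripheryResult:
    """Permutation significance of per-system core and periphery scores.

    p = (#{surrogate score >= observed} + 1) / (n_perm + 1), one-sided.
    Adjusted p-values are Bonferroni-corrected across systems; pass the
    number of subgraphs under simultaneous test as ``bonferroni_extra``
    to extend the correction across subgraphs.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    base = core_periphery_index(subgraph, partition, edge_index=edge_index)
    w, edge_index, n = _edge_weights(subgraph, edge_index)
    rng = np.random.default_rng(seed)
    n_sys = len(base.systems)
    systems, within, cross = _system_edge_masks(partition, edge_index)
    rows = np.empty((2 * n_sys, w.size))
    for i, s in enumerate(systems):
        size = partition.size(s)
        rows[i] = within[s] * (2.0 / size)
        rows[n_sys + i] = cross[s] / (size * (n - size))
    exceed = _permutation_exceedance(
        w, rows, np.concatenate([base.core, base.periphery]), n_perm, rng)
    core_pv = (exceed[:n_sys] + 1.0) / (n_perm + 1.0)
    periph_pv = (exceed[n_sys:] + 1.0) / (n_perm + 1.0)
    factor = n_sys * max(1, bonferroni_extra)
    return CorePeripheryResult(
        systems=base.systems, core=base.core, periphery=base.periphery,
        index=base.index, core_p=core_pv, periphery_p=periph_pv,
        core_p_adj=np.minimum(core_pv * factor, 1.0),
        periphery_p_adj=np.minimum(periph_pv * factor, 1.0),
    )


def system_interaction_test(
    subgraph,
    partition: SystemPartition,
    n_perm: int = 10000,
    seed: int | None = None,
    edge_index=None,
    bonferroni_extra: int = 1,
) -> pd.DataFrame:
    """Permutation test of mean within- and between-system edge weights.

    Same surrogate model as :func:`system_core_periphery_test`, but the
    statistics are the mean edge weight among a system's internal node
    pairs and among its pairs with the rest of the network.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    w, edge_index, n = _edge_weights(subgraph, edge_index)
    if partition.n_regions != n:
        raise ValueError("partition size does not match the subgraph")
    systems, within, cross = _system_edge_masks(partition, edge_index)
    n_sys = len(systems)
    rows = np.empty((2 * n_sys, w.size))
    for i, s in enumerate(systems):
        rows[i] = within[s] / max(1, int(within[s].sum()))
        rows[n_sys + i] = cross[s] / max(1, int(cross[s].sum()))
    obs = rows @ w
    obs_within, obs_between = obs[:n_sys], obs[n_sys:]
    rng = np.random.default_rng(seed)
    exceed = _permutation_exceedance(w, rows, obs, n_perm, rng)
    p_within = (exceed[:n_sys] + 1.0) / (n_perm + 1.0)
    p_between = (exceed[n_sys:] + 1.0) / (n_perm + 1.0)
    factor = len(systems) * max(1, bonferroni_extra)
    return pd.DataFrame(
        {
            "system": systems,
            "within_mean": obs_within,
            "between_mean": obs_between,
            "within_p": p_within,
            "between_p": p_between,
            "within_p_adj": np.minimum(p_within * factor, 1.0),
            "between_p_adj": np.minimum(p_between * factor, 1.0),
        }
    )


# ---------------------------------------------------------------------------
# expression contrasts


def _cohort_profile(summary: ExpressionSummary, filters: dict) -> np.ndarray:
    """Cohort-mean relative expression per subgraph under column filters."""
    means = summary.subject_means(**filters)
    profile = means.groupby("subgraph")["relative"].mean()
    return profile.sort_index().to_numpy()


def expression_hierarchy_correlation(
    summary: ExpressionSummary, grouping_a: dict, grouping_b: dict
) -> tuple[float, float]:
    """Spearman rho between two groupings' cohort-mean expression profiles.

    Groupings are column filters such as ``{"task": "taskA"}`` vs
    ``{"task": "taskB"}`` or ``{"condition": "low"}`` vs
    ``{"condition": "high"}``.
    """
    if summary.n_subgraphs < 3:
        raise ValueError("need at least 3 subgraphs")
    return spearman(_cohort_profile(summary, grouping_a),
                    _cohort_profile(summary, grouping_b))


@dataclass
class ContrastResult:
    """Per-subgraph (or per-edge) paired contrast with FDR adjustment."""

    table: pd.DataFrame
    fdr_q: float
    label_a: str
    label_b: str


def contrast_expression(
    summary: ExpressionSummary,
    grouping_a: dict,
    grouping_b: dict,
    fdr_q: float = 0.05,
) -> ContrastResult:
    """Paired t contrast of relative expression between two groupings.

    Per subgraph: subjects' mean relative expression in grouping A vs
    grouping B, two-sided paired t, Benjamini-Hochberg across subgraphs.
    """
    wide_a = summary.subject_means(**grouping_a).pivot(
        index="subject", columns="subgraph", values="relative")
    wide_b = summary.subject_means(**grouping_b).pivot(
        index="subject", columns="subgraph", values="relative")
    wide_b = wide_b.loc[wide_a.index, wide_a.columns]
    if len(wide_a) < 2:
        raise ValueError("paired contrast needs at least 2 subjects")

    t, p = stats.ttest_rel(wide_a.to_numpy(), wide_b.to_numpy(), axis=0)
    p = np.where(np.isnan(p), 1.0, p)
    t = np.where(np.isnan(t), 0.0, t)
    p_adj = bh_adjust(p)
    diff = wide_a.to_numpy().mean(axis=0) - wide_b.to_numpy().mean(axis=0)
    table = pd.DataFrame(
        {
            "subgraph": wide_a.columns.to_numpy(),
            "mean_diff": diff,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "significant": p_adj <= fdr_q,
            "direction": np.where(diff >= 0, "a>b", "b>a"),
        }
    )
    label = lambda g: ",".join(f"{k}={v}" for k, v in g.items())  # noqa: E731
    return ContrastResult(table=table, fdr_q=fdr_q,
                          label_a=label(grouping_a), label_b=label(grouping_b))


def edge_contrast(
    config: ConfigurationMatrix,
    grouping_a: dict,
    grouping_b: dict,
    fdr_q: float = 0.05,
) -> dict[str, ContrastResult]:
    """Edge-wise Fisher-Z paired contrast between two column groupings.

    For each sign channel separately: every correlation magnitude is
    r-to-Z transformed, averaged over each subject's group columns, and
    compared between groups with a paired t-test per edge; FDR across
    edges.  The table reports the mean delta-Z of significant edges via
    the ``mean_dz`` column.
    """
    meta = config.meta
    subjects = config.subjects
    if np.any(config.weights >= 1.0 - 1e-7):
        warnings.warn("correlation magnitudes at 1 clipped before the Z transform",
                      stacklevel=2)
    results = {}
    for sign in ("pos", "neg"):
        sign_mask = (meta["sign"] == sign).to_numpy()
        per_subject_a = []
        per_subject_b = []
        for subj in subjects:
            subj_mask = (meta["subject"] == subj).to_numpy()
            for filters, store in ((grouping_a, per_subject_a), (grouping_b, per_subject_b)):
                mask = sign_mask & subj_mask
                for key, value in filters.items():
                    mask &= (meta[key] == value).to_numpy()
                if not mask.any():
                    raise ValueError(
                        f"no {sign}-channel columns for subject {subj} under {filters}")
                z = fisher_z(config.weights[:, mask])
                store.append(z.mean(axis=1))
        za = np.array(per_subject_a)  # subjects x edges
        zb = np.array(per_subject_b)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_rel(za, zb, axis=0)
        p = np.where(np.isnan(p), 1.0, p)
        t = np.where(np.isnan(t), 0.0, t)
        p_adj = bh_adjust(p)
        dz = za.mean(axis=0) - zb.mean(axis=0)
        significant = p_adj <= fdr_q
        table = pd.DataFrame(
            {
                "edge": np.arange(config.n_edges),
                "node_i": config.edge_index[:, 0],
                "node_j": config.edge_index[:, 1],
                "mean_dz": dz,
                "t": t,
                "p": p,
                "p_adj": p_adj,
                "significant": significant,
                "direction": np.where(dz >= 0, "a>b", "b>a"),
            }
        )
        label = lambda g: ",".join(f"{k}={v}" for k, v in g.items())  # noqa: E731
        results[sign] = ContrastResult(table=table, fdr_q=fdr_q,
                                       label_a=label(grouping_a),
                                       label_b=label(grouping_b))
    return results
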