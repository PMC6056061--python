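"""Split-half test-retest of subgraph decompositions.

Splits configuration columns by block index, matches the two halves'
subgraphs with an optimal linear assignment, and tests matched-pair
similarity against the null of non-assigned pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .learning import NMFParameters, fit_nmf
from .networks import ConfigurationMatrix, normalize_configuration

__all__ = [
    "SubgraphMatch",
    "split_half",
    "match_subgraphs",
    "similarity_null_test",
    "split_half_reliability",
]


def split_half(
    config: ConfigurationMatrix,
    split_block: int | None = None,
    renormalize: bool = True,
) -> tuple[ConfigurationMatrix, ConfigurationMatrix]:
    """Partition observation columns into early and late block halves.

    Blocks with index < ``split_block`` go to the first half (default:
    half the distinct block indices, requiring an even count).  Both
    halves are re-normalized independently by default, so pass the raw
    (unnormalized) configuration here.
    """
    blocks = sorted(config.meta["block"].unique())
    if len(blocks) < 2:
        raise ValueError("need at least 2 blocks per condition to split")
    if split_block is None:
        if len(blocks) % 2:
            raise ValueError(
                f"odd number of blocks ({len(blocks)}); pass split_block explicitly")
        split_block = blocks[len(blocks) // 2]
    early = config.meta["block"] < split_block
    first = config.select(early.to_numpy())
    second = config.select((~early).to_numpy())
    if first.n_observations == 0 or second.n_observations == 0:
        raise ValueError(f"split_block={split_block} leaves an empty half")
    if renormalize:
        first = normalize_configuration(first)
        second = normalize_configuration(second)
    return first, second


@dataclass
class SubgraphMatch:
    """Optimal one-to-one assignment between two subgraph sets."""

    assignment: np.ndarray  # assignment[i] = matched column of W2 for W1 column i
    cost_matrix: np.ndarray  # Euclidean distances ||W1_i - W2_j||
    total_cost: float
    correlations: np.ndarray  # Pearson similarity of matched pairs
    null_correlations: np.ndarray  # all m(m-1) non-assigned pair similarities

    @property
    def m(self) -> int:
        return self.assignment.size


def match_subgraphs(W1: np.ndarray, W2: np.ndarray) -> SubgraphMatch:
    """Hungarian matching of subgraph columns by Euclidean distance.

    The matched-pair Pearson correlations quantify similarity; the
    correlations of every non-assigned pair form the chance-level null.
    """
    W1 = np.asarray(W1, dtype=float)
    W2 = np.asarray(W2, dtype=float)
    if W1.shape != W2.shape:
        raise ValueError("subgraph matrices must have equal shapes")
    m = W1.shape[1]
    cost = cdist(W1.T, W2.T, metric="euclidean")
    rows, cols = linear_sum_assignment(cost)
    assignment = np.empty(m, dtype=int)
    assignment[rows] = cols

    corr_all = _column_correlations(W1, W2)
    matched = corr_all[np.arange(m), assignment]
    null_mask = np.ones((m, m), dtype=bool)
    null_mask[np.arange(m), assignment] = False
    return SubgraphMatch(
        assignment=assignment,
        cost_matrix=cost,
        total_cost=float(cost[rows, cols].sum()),
        correlations=matched,
        null_correlations=corr_all[null_mask],
    )


def _column_correlations(W1: np.ndarray, W2: np.ndarray) -> np.ndarray:
    a = W1 - W1.mean(axis=0)
    b = W2 - W2.mean(axis=0)
    sa = np.linalg.norm(a, axis=0)
    sb = np.linalg.norm(b, axis=0)
    sa[sa == 0] = np.inf
    sb[sb == 0] = np.inf
    return (a.T @ b) / np.outer(sa, sb)


def similarity_null_test(match: SubgraphMatch, alpha: float = 0.05) -> pd.DataFrame:
    """Flag matched pairs exceeding the non-assigned-pair null bound.

    The bound is the (1 - alpha/m) quantile of the null correlations
    (Bonferroni over the m matched pairs).
    """
    if match.m < 2:
        raise ValueError("need at least 2 subgraphs for a null distribution")
    bound = float(np.quantile(match.null_correlations, 1.0 - alpha / match.m))
    idx = np.arange(match.m)
    return pd.DataFrame(
        {
            "pair_first": idx,
            "pair_second": match.assignment,
            "distance": match.cost_matrix[idx, match.assignment],
            "correlation": match.correlations,
            "null_bound": bound,
            "reliable": match.correlations > bound,
        }
    )


def split_half_reliability(
    config: ConfigurationMatrix,
    params: NMFParameters,
    seed: int | None = None,
    split_block: int | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, SubgraphMatch]:
    """Full split-half pipeline on a raw configuration matrix.

    Both halves are decomposed with the same (m, beta, alpha) as the
    full-data run; only the seeds differ (spawned from ``seed``).
    """
    first, second = split_half(config, split_block=split_block)
    seeds = np.random.SeedSequence(params.seed if seed is None else seed).spawn(2)
    fit1 = fit_nmf(first.weights, NMFParameters(
        m=params.m, beta=params.beta, alpha=params.alpha, max_iter=params.max_iter,
        tol=params.tol, seed=int(seeds[0].generate_state(1)[0])))
    fit2 = fit_nmf(second.weights, NMFParameters(
        m=params.m, beta=params.beta, alpha=params.alpha, max_iter=params.max_iter,
        tol=params.tol, seed=int(seeds[1].generate_state(1)[0])))
    match = match_subgraphs(fit1.W, fit2.W)
    return similarity_null_test(match, alpha=alpha), match
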