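"""Regularized NMF of the configuration matrix.

Objective, for A (E x T), W (E x m), H (m x T), all non-negative:

    J(W, H) = 1/2 ||A - WH||_F^2 + alpha ||W||_F^2 + beta sum_t (sum_k H[k,t])^2

fit with alternating non-negative least squares (block principal
pivoting), plus random-sampling cross-validated parameter selection and
consensus clustering over repeated runs.  A multiplicative-update solver
of the same objective is provided as an independent reference
implementation for validation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._nnls import nnls_bpp
from .networks import ConfigurationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NMFParameters",
    "SubgraphDecomposition",
    "CVResult",
    "ConsensusResult",
    "nmf_objective",
    "fit_nmf",
    "fit_nmf_multiplicative",
    "fit_expression",
    "sample_parameters",
    "cross_validate",
    "select_optimum",
    "consensus_cluster",
]

DEFAULT_PARAMETER_RANGES = {"m": (3, 50), "beta": (0.01, 5.0), "alpha": (0.01, 5.0)}


@dataclass(frozen=True)
class NMFParameters:
    """Factorization hyper-parameters (m, beta, alpha)."""

    m: int
    beta: float = 0.0
    alpha: float = 0.0
    max_iter: int = 100
    tol: float = 1e-6
    seed: int | None = None

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.beta < 0 or self.alpha < 0:
            raise ValueError("beta and alpha must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class SubgraphDecomposition:
    """Result of one factorization run."""

    W: np.ndarray  # E x m
    H: np.ndarray  # m x T
    objective_trace: np.ndarray  # initial value + one per iteration
    params: NMFParameters

    @property
    def m(self) -> int:
        return self.W.shape[1]


@dataclass
class CVResult:
    """Cross-validation errors for sampled parameter sets."""

    table: pd.DataFrame  # columns: m, beta, alpha, cv_error
    folds: list[list]  # subject ids per fold


@dataclass
class ConsensusResult:
    """Consensus subgraphs aggregated over repeated runs."""

    W: np.ndarray  # E x m, columns unit-L2
    H: np.ndarray  # m x T
    n_runs: int
    run_seeds: list[int]
    params: NMFParameters
    run_decompositions: list[SubgraphDecomposition] = field(default_factory=list, repr=False)


def _as_array(config) -> np.ndarray:
    if isinstance(config, ConfigurationMatrix):
        return config.weights
    return np.asarray(config, dtype=float)


def nmf_objective(A, W, H, alpha: float = 0.0, beta: float = 0.0) -> float:
    """Evaluate the regularized factorization objective."""
    A, W, H = (np.asarray(x, dtype=float) for x in (A, W, H))
    for name, x in (("A", A), ("W", W), ("H", H)):
        if np.any(x < 0):
            raise ValueError(f"{name} must be non-negative")
    resid = A - W @ H
    value = 0.5 * float(np.sum(resid * resid))
    if alpha:
        value += alpha * float(np.sum(W * W))
    if beta:
        col_l1 = H.sum(axis=0)
        value += beta * float(np.sum(col_l1 * col_l1))
    return value


def _init_factors(shape_w, shape_h, seed):
    rng = np.random.default_rng(seed)
    W = rng.uniform(0.0, 1.0, size=shape_w)
    H = rng.uniform(0.0, 1.0, size=shape_h)
    return W, H


def _check_problem(A: np.ndarray, m: int) -> None:
    if not np.all(np.isfinite(A)):
        raise ValueError("A contains non-finite entries")
    if np.any(A < 0):
        raise ValueError("A must be non-negative")
    if m >= min(A.shape):
        raise ValueError(f"m={m} must be < min(E, T)={min(A.shape)}")


def _update_h(A, W, beta):
    m = W.shape[1]
    CtC = W.T @ W
    if beta:
        CtC = CtC + 2.0 * beta * np.ones((m, m))
    return nnls_bpp(CtC, W.T @ A)


def _update_w(A, H, alpha):
    m = H.shape[0]
    CtC = H @ H.T
    if alpha:
        CtC = CtC + 2.0 * alpha * np.eye(m)
    return nnls_bpp(CtC, H @ A.T).T


def fit_nmf(config, params: NMFParameters) -> SubgraphDecomposition:
    """Alternating non-negative least squares with block pivoting.

    W and H are initialized uniformly at random on [0, 1] from
    ``params.seed``; iteration stops at ``params.max_iter`` or when the
    relative objective change drops below ``params.tol``.  Each ANLS
    sweep solves both subproblems exactly, so the objective trace is
    non-increasing.
    """
    A = _as_array(config)
    _check_problem(A, params.m)
    W, H = _init_factors((A.shape[0], params.m), (params.m, A.shape[1]), params.seed)
    trace = [nmf_objective(A, W, H, params.alpha, params.beta)]
    for _ in range(params.max_iter):
        H = _update_h(A, W, params.beta)
        W = _update_w(A, H, params.alpha)
        trace.append(nmf_objective(A, W, H, params.alpha, params.beta))
        if abs(trace[-2] - trace[-1]) <= params.tol * max(1.0, abs(trace[-2])):
            break
    return SubgraphDecomposition(W=W, H=H, objective_trace=np.array(trace), params=params)


def fit_nmf_multiplicative(config, params: NMFParameters) -> SubgraphDecomposition:
    """Multiplicative-update solver of the same objective.

    Independent of the ANLS path; used as a reference implementation for
    validating solver correctness.  Initialization is identical to
    :func:`fit_nmf` for the same seed so runs are directly comparable.
    """
    A = _as_array(config)
    _check_problem(A, params.m)
    m = params.m
    W, H = _init_factors((A.shape[0], m), (m, A.shape[1]), params.seed)
    eps = 1e-12
    ones = np.ones((m, m))
    trace = [nmf_objective(A, W, H, params.alpha, params.beta)]
    for _ in range(params.max_iter):
        numer = W.T @ A
        denom = W.T @ W @ H + eps
        if params.beta:
            denom = denom + 2.0 * params.beta * (ones @ H)
        H = H * numer / denom
        numer = A @ H.T
        denom = W @ (H @ H.T) + eps
        if params.alpha:
            denom = denom + 2.0 * params.alpha * W
        W = W * numer / denom
        trace.append(nmf_objective(A, W, H, params.alpha, params.beta))
        if abs(trace[-2] - trace[-1]) <= params.tol * max(1.0, abs(trace[-2])):
            break
    return SubgraphDecomposition(W=W, H=H, objective_trace=np.array(trace), params=params)


def fit_expression(config, W_fixed: np.ndarray, beta: float = 0.0) -> np.ndarray:
    """Solve the H-subproblem with W frozen (out-of-sample projection).

    All-zero columns of W receive zero coefficients (logged) rather than
    propagating a singular system.
    """
    A = _as_array(config)
    W = np.asarray(W_fixed, dtype=float)
    if np.any(W < 0):
        raise ValueError("W_fixed must be non-negative")
    live = W.sum(axis=0) > 0
    H = np.zeros((W.shape[1], A.shape[1]))
    if not live.all():
        logger.warning("%d zero subgraph column(s); their coefficients set to 0",
                       int((~live).sum()))
    if live.any():
        H[live] = _update_h(A, W[:, live], beta)
    return H


def sample_parameters(
    n_samples: int,
    ranges: dict | None = None,
    seed: int | None = None,
    max_iter: int = 100,
) -> list[NMFParameters]:
    """Draw (m, beta, alpha) sets from independent uniform distributions.

    m is integer-uniform over its inclusive range; beta and alpha are
    continuous-uniform.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    ranges = {**DEFAULT_PARAMETER_RANGES, **(ranges or {})}
    for name, (lo, hi) in ranges.items():
        if hi < lo:
            raise ValueError(f"empty range for {name}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    m_lo, m_hi = ranges["m"]
    ms = rng.integers(int(m_lo), int(m_hi) + 1, size=n_samples)
    betas = rng.uniform(*ranges["beta"], size=n_samples)
    alphas = rng.uniform(*ranges["alpha"], size=n_samples)
    return [
        NMFParameters(m=int(ms[i]), beta=float(betas[i]), alpha=float(alphas[i]),
                      max_iter=max_iter)
        for i in range(n_samples)
    ]


def _subject_folds(subjects: list, n_folds: int, rng: np.random.Generator) -> list[list]:
    order = list(rng.permutation(len(subjects)))
    return [
        [subjects[i] for i in chunk]
        for chunk in np.array_split(order, n_folds)
    ]


def cross_validate(
    config: ConfigurationMatrix,
    param_sets: list[NMFParameters],
    n_folds: int = 4,
    seed: int | None = None,
) -> CVResult:
    """Leave-subjects-out cross-validation of sampled parameter sets.

    For every parameter set and fold, W is fit on the training subjects'
    columns and the held-out error ||A_held - W H_held||_F^2 is computed
    after projecting held-out columns onto W.
    """
    subjects = config.subjects
    if n_folds < 2 or n_folds > len(subjects):
        raise ValueError("n_folds must be between 2 and the number of subjects")
    master = np.random.SeedSequence(seed)
    fold_rng = np.random.default_rng(master.spawn(1)[0])
    folds = _subject_folds(subjects, n_folds, fold_rng)
    if any(len(f) == 0 for f in folds):
        raise ValueError("a fold has zero subjects")
    subj_col = config.meta["subject"].to_numpy()

    # one seed per fold, shared across parameter sets: identical parameter
    # sets then yield identical errors
    fold_seeds = [int(s.generate_state(1)[0]) for s in master.spawn(n_folds)]
    rows = []
    for params in param_sets:
        fold_errors = []
        for f_idx, held in enumerate(folds):
            held_mask = np.isin(subj_col, held)
            A_train = config.weights[:, ~held_mask]
            A_held = config.weights[:, held_mask]
            run_params = replace(params, seed=fold_seeds[f_idx])
            fit = fit_nmf(A_train, run_params)
            H_held = fit_expression(A_held, fit.W, params.beta)
            resid = A_held - fit.W @ H_held
            fold_errors.append(float(np.sum(resid * resid)))
        rows.append({"m": params.m, "beta": params.beta, "alpha": params.alpha,
                     "cv_error": float(np.mean(fold_errors))})
    return CVResult(table=pd.DataFrame(rows), folds=folds)


def select_optimum(cv_result: CVResult, percentile: float = 5.0) -> NMFParameters:
    """Average the parameter sets in the bottom error percentile.

    m is rounded half-up to the nearest integer; beta and alpha are plain
    means over the selected sets.
    """
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    table = cv_result.table
    if len(table) == 0:
        raise ValueError("empty CV result")
    threshold = np.percentile(table["cv_error"], percentile)
    selected = table[table["cv_error"] <= threshold]
    if len(selected) == 0:  # pragma: no cover - <= percentile always selects >= 1
        raise ValueError("no parameter sets below the percentile threshold")
    m_opt = int(np.floor(selected["m"].mean() + 0.5))
    return NMFParameters(m=m_opt, beta=float(selected["beta"].mean()),
                         alpha=float(selected["alpha"].mean()))


def consensus_cluster(
    config,
    params: NMFParameters,
    R: int,
    seed: int | None = None,
    keep_runs: bool = False,
) -> ConsensusResult:
    """Consensus subgraphs over R repeated factorization runs.

    Each run's W columns are L2-normalized (removing the scale
    degeneracy) and concatenated into an E x (R*m) aggregate that is
    factorized again at rank m; consensus coefficients come from
    projecting the original matrix onto the consensus subgraphs.
    """
    if R < 2:
        raise ValueError("R must be >= 2")
    A = _as_array(config)
    master = np.random.SeedSequence(params.seed if seed is None else seed)
    n_final_attempts = 5
    children = master.spawn(R + n_final_attempts)
    run_seeds = [int(c.generate_state(1)[0]) for c in children]

    blocks = []
    runs = []
    for r in range(R):
        run_params = replace(params, seed=run_seeds[r])
        try:
            fit = fit_nmf(A, run_params)
        except Exception as exc:  # noqa: BLE001 - annotate failing run index
            raise RuntimeError(f"consensus run {r} failed") from exc
        W = fit.W.copy()
        norms = np.linalg.norm(W, axis=0)
        norms[norms == 0] = 1.0
        blocks.append(W / norms)
        if keep_runs:
            runs.append(fit)
    aggregate = np.hstack(blocks)

    # the random-init final factorization occasionally zeroes a column;
    # retry with a fresh spawned seed rather than returning a dead subgraph
    for attempt in range(n_final_attempts):
        final_params = replace(params, seed=run_seeds[R + attempt])
        consensus_fit = fit_nmf(aggregate, final_params)
        norms = np.linalg.norm(consensus_fit.W, axis=0)
        if np.all(norms > 0):
            break
    W_c = consensus_fit.W.copy()
    dead = norms == 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} empty consensus subgraph(s)", stacklevel=2)
        norms[dead] = 1.0
    W_c /= norms
    H_c = fit_expression(A, W_c, params.beta)
    return ConsensusResult(W=W_c, H=H_c, n_runs=R, run_seeds=run_seeds[:R],
                           params=params, run_decompositions=runs)
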