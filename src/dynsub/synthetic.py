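"""Synthetic cohort generator with planted subgraph structure.

Produces annotated regional time series, a node-to-system partition and
per-trial behavior tables from a fully specified generative model, so
the whole pipeline can be exercised and validated without external data.
The generative choices (multivariate normal blocks, rank-1 community
subgraphs, linear reaction-time coupling) are stand-ins for undeposited
recordings and are documented as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .networks import RegionalTimeSeries, SystemPartition, edge_list

__all__ = [
    "StudyDesign",
    "GroundTruth",
    "generate_design",
    "make_partition",
    "make_ground_truth",
    "generate_bold",
    "generate_behavior",
    "simulate_cohort",
]

#: smallest eigenvalue allowed in an assembled block covariance
EIGENVALUE_FLOOR = 1e-6

DEFAULT_TASKS = ("taskA", "taskB")
DEFAULT_CONDITIONS = ("fixation", "low", "high")


@dataclass(frozen=True)
class StudyDesign:
    """Factorial block design of the study.

    Defaults follow the reference design: 28 subjects x 2 tasks x 3
    conditions x 6 blocks x 20 samples per block over 262 regions
    grouped into 9 systems, i.e. 36 block matrices per subject.
    """

    n_subjects: int = 28
    tasks: tuple = DEFAULT_TASKS
    conditions: tuple = DEFAULT_CONDITIONS
    blocks_per_condition: int = 6
    samples_per_block: int = 20
    n_regions: int = 262
    n_systems: int = 9
    seed: int = 0

    def __post_init__(self):
        counts = {
            "n_subjects": self.n_subjects,
            "blocks_per_condition": self.blocks_per_condition,
            "samples_per_block": self.samples_per_block,
            "n_regions": self.n_regions,
            "n_systems": self.n_systems,
        }
        for name, value in counts.items():
            if int(value) < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if not self.tasks or not self.conditions:
            raise ValueError("tasks and conditions must be non-empty")
        if self.n_systems > self.n_regions:
            raise ValueError("n_systems cannot exceed n_regions")

    @property
    def subjects(self) -> list[str]:
        width = len(str(self.n_subjects - 1))
        return [f"sub{idx:0{width}d}" for idx in range(self.n_subjects)]

    @property
    def blocks_per_subject(self) -> int:
        return len(self.tasks) * len(self.conditions) * self.blocks_per_condition

    @property
    def n_edges(self) -> int:
        return self.n_regions * (self.n_regions - 1) // 2

    @property
    def n_observations(self) -> int:
        # two sign channels per block
        return self.n_subjects * self.blocks_per_subject * 2

    def cells(self) -> pd.DataFrame:
        """Every (subject, task, condition, block) cell exactly once."""
        rows = [
            {"subject": subj, "task": task, "condition": cond, "block": block}
            for subj in self.subjects
            for task in self.tasks
            for cond in self.conditions
            for block in range(self.blocks_per_condition)
        ]
        return pd.DataFrame(rows)


def generate_design(n_subjects: int = 28, seed: int = 0, **overrides) -> StudyDesign:
    """Build a :class:`StudyDesign`; extra keyword fields override defaults."""
    return StudyDesign(n_subjects=n_subjects, seed=seed, **overrides)


def make_partition(design: StudyDesign) -> SystemPartition:
    """Contiguous near-equal split of regions into labelled systems."""
    bounds = np.linspace(0, design.n_regions, design.n_systems + 1).astype(int)
    labels = np.empty(design.n_regions, dtype=object)
    for s in range(design.n_systems):
        labels[bounds[s]:bounds[s + 1]] = f"sys{s:02d}"
    return SystemPartition(labels=labels)


@dataclass
class GroundTruth:
    """Planted structure behind a synthetic cohort.

    ``expression_pos``/``expression_neg`` hold one non-negative
    coefficient per subgraph per design cell (row order matches
    ``design.cells()``); the signed channel whose coefficient dominates
    determines whether the planted covariance contribution adds or
    subtracts.
    """

    planted_subgraphs: np.ndarray  # (k, N, N) symmetric, zero diagonal
    expression_pos: np.ndarray  # (k, n_cells) >= 0
    expression_neg: np.ndarray  # (k, n_cells) >= 0
    behavior_effect: np.ndarray  # (k,) RT-cost coupling per subgraph
    noise_sd: float
    seed: int

    def __post_init__(self):
        self.planted_subgraphs = np.asarray(self.planted_subgraphs, dtype=float)
        self.expression_pos = np.asarray(self.expression_pos, dtype=float)
        self.expression_neg = np.asarray(self.expression_neg, dtype=float)
        self.behavior_effect = np.asarray(self.behavior_effect, dtype=float)
        if self.planted_subgraphs.ndim != 3:
            raise ValueError("planted_subgraphs must be (k, N, N)")
        for w in self.planted_subgraphs:
            if not np.allclose(w, w.T):
                raise ValueError("planted subgraphs must be symmetric")
            if np.any(np.diag(w) != 0):
                raise ValueError("planted subgraphs must have zero diagonal")
            if np.any(w < 0):
                raise ValueError("planted subgraphs must be non-negative")
        if np.any(self.expression_pos < 0) or np.any(self.expression_neg < 0):
            raise ValueError("planted expression must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def n_subgraphs(self) -> int:
        return self.planted_subgraphs.shape[0]

    def relative_expression(self) -> np.ndarray:
        return self.expression_pos - self.expression_neg

    def planted_edge_vectors(self) -> np.ndarray:
        """Planted subgraphs vectorized over upper-triangle edges, (E, k)."""
        n = self.planted_subgraphs.shape[1]
        iu, ju = np.triu_indices(n, k=1)
        return self.planted_subgraphs[:, iu, ju].T


def make_ground_truth(
    design: StudyDesign,
    n_subgraphs: int,
    seed: int | None = None,
    expression_scale: float = 0.6,
    subject_gain_range: tuple[float, float] = (0.5, 1.5),
    negative_fraction: float = 0.35,
    membership_floor: float = 0.0,
    ensure_negative: bool = True,
    noise_sd: float = 0.0,
    behavior_effect: np.ndarray | float = 0.0,
) -> GroundTruth:
    """Plant rank-1 community subgraphs aligned to the system partition.

    Subgraph k is the rank-1 pattern u_k u_k' (zero diagonal) with
    membership u_k = 1 on system k's nodes and ``membership_floor``
    elsewhere; with the default floor of 0 each subgraph is a pure
    community block.  A positive floor spreads planted weight over every
    edge, which keeps the factorization problem identifiable at the true
    rank (otherwise the rectified sampling noise on never-planted edges
    forms an extra diffuse component competing with the planted ones).

    Per-cell expressions are random, carry a per-subject gain (so
    expression varies across subjects), and a fraction of cells express
    each subgraph through the negative channel, planting genuine
    anticorrelations.  With ``ensure_negative`` (and a positive
    ``negative_fraction``) every cell expresses at least one subgraph
    negatively, so the negative sign channel is never empty.
    """
    if n_subgraphs < 1:
        raise ValueError("need at least one planted subgraph")
    if n_subgraphs > design.n_systems:
        raise ValueError("at most one planted subgraph per system")
    if not 0.0 <= membership_floor < 1.0:
        raise ValueError("membership_floor must be in [0, 1)")
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    partition = make_partition(design)

    subgraphs = np.zeros((n_subgraphs, design.n_regions, design.n_regions))
    systems = partition.systems
    for k in range(n_subgraphs):
        u = np.full(design.n_regions, membership_floor)
        u[partition.members(systems[k])] = 1.0
        subgraphs[k] = np.outer(u, u)
        np.fill_diagonal(subgraphs[k], 0.0)

    cells = design.cells()
    n_cells = len(cells)
    subj_index = pd.Categorical(
        cells["subject"], categories=design.subjects
    ).codes
    gains = rng.uniform(*subject_gain_range, size=(n_subgraphs, design.n_subjects))

    magnitude = rng.uniform(0.3, 1.0, size=(n_subgraphs, n_cells)) * expression_scale
    magnitude *= gains[:, subj_index]
    sign_is_neg = rng.random((n_subgraphs, n_cells)) < negative_fraction
    if ensure_negative and negative_fraction > 0:
        all_pos = ~sign_is_neg.any(axis=0)
        weakest = magnitude[:, all_pos].argmin(axis=0)
        sign_is_neg[weakest, np.where(all_pos)[0]] = True
    expression_pos = np.where(~sign_is_neg, magnitude, 0.0)
    expression_neg = np.where(sign_is_neg, magnitude, 0.0)

    effect = np.broadcast_to(
        np.atleast_1d(np.asarray(behavior_effect, dtype=float)), (n_subgraphs,)
    ).copy()
    return GroundTruth(
        planted_subgraphs=subgraphs,
        expression_pos=expression_pos,
        expression_neg=expression_neg,
        behavior_effect=effect,
        noise_sd=noise_sd,
        seed=seed,
    )


def _block_covariance(truth: GroundTruth, cell_idx: int, n_regions: int) -> np.ndarray:
    """Identity plus expression-weighted planted structure, PD-floored."""
    delta = truth.expression_pos[:, cell_idx] - truth.expression_neg[:, cell_idx]
    sigma = np.eye(n_regions)
    for k in range(truth.n_subgraphs):
        if delta[k] != 0.0:
            sigma = sigma + delta[k] * truth.planted_subgraphs[k]
    sigma = 0.5 * (sigma + sigma.T)
    evals, evecs = np.linalg.eigh(sigma)
    if evals[0] < EIGENVALUE_FLOOR:
        evals = np.maximum(evals, EIGENVALUE_FLOOR)
        sigma = (evecs * evals) @ evecs.T
    return sigma


def generate_bold(
    design: StudyDesign,
    truth: GroundTruth,
    lead_samples: int = 4,
) -> list[RegionalTimeSeries]:
    """Sample per-block multivariate-normal series for every subject.

    Each block is drawn from a zero-mean normal whose covariance is the
    identity plus the expression-weighted sum of planted subgraphs
    (negative-channel expression subtracts), floored to be positive
    definite; ``truth.noise_sd`` adds white measurement noise.  Every
    block is preceded by ``lead_samples`` extra samples from the same
    distribution so downstream window shifts stay inside the block; the
    annotated onset points at the block start and ``n_samples`` at the
    post-lead window length.  One RNG stream is spawned per subject from
    the master seed.
    """
    if truth.planted_subgraphs.shape[1] != design.n_regions:
        raise ValueError("ground-truth matrices are not sized to the design")
    cells = design.cells()
    master = np.random.SeedSequence(truth.seed)
    streams = master.spawn(design.n_subjects)

    block_len = design.samples_per_block + lead_samples
    chol_cache: dict[int, np.ndarray] = {}
    series_list = []
    for s_idx, subj in enumerate(design.subjects):
        rng = np.random.default_rng(streams[s_idx])
        idx = np.where(cells["subject"].to_numpy() == subj)[0]
        chunks = []
        annotations = []
        onset = 0
        for cell_idx in idx:
            sigma = _block_covariance(truth, cell_idx, design.n_regions)
            key = hash(sigma.tobytes())
            if key not in chol_cache:
                chol_cache[key] = np.linalg.cholesky(sigma)
            chol = chol_cache[key]
            z = rng.standard_normal((design.n_regions, block_len))
            x = chol @ z
            if truth.noise_sd > 0:
                x = x + truth.noise_sd * rng.standard_normal(x.shape)
            chunks.append(x)
            row = cells.iloc[cell_idx]
            annotations.append(
                {"task": row["task"], "condition": row["condition"],
                 "block": int(row["block"]),
                 # onset marks the block start; the downstream window shift
                 # (<= lead_samples) stays inside this block
                 "onset_sample": onset,
                 "n_samples": design.samples_per_block}
            )
            onset += block_len
        series_list.append(
            RegionalTimeSeries(
                subject_id=subj,
                values=np.hstack(chunks),
                annotations=pd.DataFrame(annotations),
            )
        )
    return series_list


def generate_behavior(
    design: StudyDesign,
    truth: GroundTruth,
    expression: np.ndarray | None = None,
    baseline_ms: float = 500.0,
    condition_offset_ms: float = 100.0,
    rt_noise_sd: float = 25.0,
    p_correct: float = 0.92,
    trials_per_block: int = 20,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-trial reaction times coupled to planted subgraph expression.

    RT = baseline + offset(high condition) + sum_k behavior_effect[k] *
    (subject's planted relative expression of subgraph k in that cell) +
    noise.  Only the low/high conditions carry trials.  ``expression``
    may override the planted relative expression with a (k, n_cells)
    array (e.g. a decomposition's coefficients).
    """
    if baseline_ms <= 0:
        raise ValueError("baseline_ms must be positive")
    rel = truth.relative_expression() if expression is None else np.asarray(expression)
    cells = design.cells()
    if rel.shape[1] != len(cells):
        raise ValueError("expression not aligned with design cells")
    rng = np.random.default_rng(truth.seed + 7919 if seed is None else seed)

    rows = []
    for cell_idx, row in cells.iterrows():
        if row["condition"] == "fixation":
            continue
        shift = float(truth.behavior_effect @ rel[:, cell_idx])
        offset = condition_offset_ms if row["condition"] == "high" else 0.0
        rts = baseline_ms + offset + shift + rt_noise_sd * rng.standard_normal(trials_per_block)
        rts = np.maximum(rts, 50.0)
        correct = rng.random(trials_per_block) < p_correct
        for trial in range(trials_per_block):
            rows.append(
                {"subject": row["subject"], "task": row["task"],
                 "condition": row["condition"], "block": int(row["block"]),
                 "trial": trial, "rt_ms": float(rts[trial]),
                 "correct": int(correct[trial])}
            )
    return pd.DataFrame(rows)


@dataclass
class SyntheticCohort:
    """Bundle of everything one simulated study produces."""

    design: StudyDesign
    truth: GroundTruth
    partition: SystemPartition
    series: list[RegionalTimeSeries]
    behavior: pd.DataFrame = field(repr=False, default=None)


def simulate_cohort(
    design: StudyDesign | None = None,
    n_subgraphs: int = 4,
    seed: int | None = None,
    lead_samples: int = 4,
    with_behavior: bool = True,
    **truth_kwargs,
) -> SyntheticCohort:
    """One-call synthetic study: design, truth, series, behavior."""
    design = design or StudyDesign()
    truth = make_ground_truth(design, n_subgraphs, seed=seed, **truth_kwargs)
    series = generate_bold(design, truth, lead_samples=lead_samples)
    behavior = generate_behavior(design, truth) if with_behavior else None
    return SyntheticCohort(
        design=design,
        truth=truth,
        partition=make_partition(design),
        series=series,
        behavior=behavior,
    )


def truth_expression_matrix(design: StudyDesign, truth: GroundTruth) -> tuple[np.ndarray, pd.DataFrame]:
    """Planted expression laid out like a decomposition H over config columns.

    Returns (H, meta) where H is (k, T) with T = 2 x n_cells and meta
    matches the configuration-matrix column ordering (subject, task,
    condition, block, sign).
    """
    cells = design.cells()
    metas = []
    cols = []
    for cell_idx, row in cells.iterrows():
        for sign in ("pos", "neg"):
            source = truth.expression_pos if sign == "pos" else truth.expression_neg
            cols.append(source[:, cell_idx])
            metas.append({"subject": row["subject"], "task": row["task"],
                          "condition": row["condition"], "block": int(row["block"]),
                          "sign": sign})
    return np.array(cols).T, pd.DataFrame(metas)
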