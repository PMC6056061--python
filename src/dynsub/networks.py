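"""Signed block-network construction.

Turns annotated regional time series into per-block correlation networks,
splits them by sign into non-negative positive/negative channels, and
assembles the edge-by-observation configuration matrix consumed by the
factorization stage.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegionalTimeSeries",
    "BlockSegment",
    "BlockNetwork",
    "SignedNetworkSet",
    "ConfigurationMatrix",
    "SystemPartition",
    "SIGN_CHANNELS",
    "edge_list",
    "vectorize_matrix",
    "devectorize",
    "extract_blocks",
    "block_correlation",
    "sign_split",
    "assemble_configuration",
    "normalize_configuration",
    "summarize_edge_strength",
    "EdgeStrengthSummary",
]

#: order of the two sign channels in configuration-matrix columns
SIGN_CHANNELS = ("pos", "neg")

ANNOTATION_COLUMNS = ("task", "condition", "block", "onset_sample", "n_samples")


@dataclass
class RegionalTimeSeries:
    """One subject's regions x samples signal plus block annotations."""

    subject_id: str
    values: np.ndarray
    annotations: pd.DataFrame
    sampling_interval: float = 1.5

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a regions x samples matrix")
        missing = set(ANNOTATION_COLUMNS) - set(self.annotations.columns)
        if missing:
            raise ValueError(f"annotations missing columns: {sorted(missing)}")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class BlockSegment:
    """Windowed samples for one annotated block."""

    subject_id: str
    task: str
    condition: str
    block: int
    values: np.ndarray  # regions x n_samples


@dataclass
class BlockNetwork:
    """Signed split of one block's correlation matrix."""

    subject_id: str
    task: str
    condition: str
    block: int
    positive: np.ndarray
    negative: np.ndarray


@dataclass
class SignedNetworkSet:
    """All per-block positive/negative edge-weight matrices of a cohort."""

    networks: list[BlockNetwork] = field(default_factory=list)

    def __iter__(self):
        return iter(self.networks)

    def __len__(self) -> int:
        return len(self.networks)

    def append(self, network: BlockNetwork) -> None:
        self.networks.append(network)


@dataclass
class SystemPartition:
    """Assignment of every region to exactly one labelled system."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one entry per region")

    @property
    def n_regions(self) -> int:
        return self.labels.size

    @property
    def systems(self) -> list:
        return sorted(set(self.labels.tolist()))

    def members(self, system) -> np.ndarray:
        return np.where(self.labels == system)[0]

    def size(self, system) -> int:
        return int((self.labels == system).sum())


@dataclass
class ConfigurationMatrix:
    """Non-negative edges x observations matrix with column metadata.

    Rows follow the fixed upper-triangle edge order (i < j, row-major);
    columns carry (subject, task, condition, block, sign) metadata.
    """

    weights: np.ndarray  # E x T, non-negative
    edge_index: np.ndarray  # E x 2, i < j
    meta: pd.DataFrame  # T rows

    def __post_init__(self):
        self.weights = np.asarray(self.weights)
        self.edge_index = np.asarray(self.edge_index)
        if self.weights.ndim != 2:
            raise ValueError("weights must be 2-D")
        if self.edge_index.shape != (self.weights.shape[0], 2):
            raise ValueError("edge_index inconsistent with weight rows")
        if len(self.meta) != self.weights.shape[1]:
            raise ValueError("meta inconsistent with weight columns")
        if np.any(self.weights < 0):
            raise ValueError("configuration weights must be non-negative")

    @property
    def n_edges(self) -> int:
        return self.weights.shape[0]

    @property
    def n_observations(self) -> int:
        return self.weights.shape[1]

    @property
    def n_regions(self) -> int:
        return int(self.edge_index.max()) + 1

    @property
    def subjects(self) -> list:
        return list(pd.unique(self.meta["subject"]))

    def column_matrix(self, t: int) -> np.ndarray:
        """Reconstitute observation column ``t`` as a symmetric matrix."""
        return devectorize(self.weights[:, t], self.n_regions)

    def select(self, mask) -> "ConfigurationMatrix":
        mask = np.asarray(mask)
        return ConfigurationMatrix(
            weights=self.weights[:, mask],
            edge_index=self.edge_index,
            meta=self.meta.loc[mask].reset_index(drop=True),
        )

    def task_mask(self) -> np.ndarray:
        """Boolean mask over columns excluding fixation observations."""
        return (self.meta["condition"] != "fixation").to_numpy()


def edge_list(n_regions: int) -> np.ndarray:
    """Upper-triangle node pairs (i < j) in row-major order."""
    iu, ju = np.triu_indices(n_regions, k=1)
    return np.column_stack([iu, ju])


def vectorize_matrix(matrix: np.ndarray) -> np.ndarray:
    """Vectorize the strict upper triangle of a square matrix."""
    matrix = np.asarray(matrix)
    n = matrix.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    return matrix[iu, ju]


def devectorize(edges: np.ndarray, n_regions: int) -> np.ndarray:
    """Inverse of :func:`vectorize_matrix` (zero diagonal)."""
    out = np.zeros((n_regions, n_regions), dtype=float)
    iu, ju = np.triu_indices(n_regions, k=1)
    out[iu, ju] = edges
    out[ju, iu] = edges
    return out


def extract_blocks(series: RegionalTimeSeries, shift_samples: int = 4) -> list[BlockSegment]:
    """Cut annotated block windows out of a series after a fixed shift.

    Each annotated block of length L starting at onset o yields the
    samples [o + shift, o + shift + L).
    """
    if shift_samples < 0:
        raise ValueError("shift_samples must be >= 0")
    segments = []
    for row in series.annotations.itertuples(index=False):
        start = int(row.onset_sample) + shift_samples
        stop = start + int(row.n_samples)
        if start < 0 or stop > series.n_samples:
            raise ValueError(
                f"shifted window [{start}, {stop}) exceeds series of "
                f"{series.n_samples} samples (subject {series.subject_id}, "
                f"task {row.task}, condition {row.condition}, block {row.block})"
            )
        segments.append(
            BlockSegment(
                subject_id=series.subject_id,
                task=row.task,
                condition=row.condition,
                block=int(row.block),
                values=series.values[:, start:stop],
            )
        )
    return segments


def block_correlation(segment_values: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of one block's regional signals.

    Regions with constant signal get zero-weight edges (and a warning)
    rather than NaNs; the diagonal is kept at one.
    """
    x = np.asarray(segment_values, dtype=float)
    if x.ndim != 2 or x.shape[1] < 3:
        raise ValueError("need a regions x samples matrix with >= 3 samples")
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant-signal region(s); their edges set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr = np.asarray(corr, dtype=float)
    corr[np.isnan(corr)] = 0.0
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    np.clip(corr, -1.0, 1.0, out=corr)
    return corr


def sign_split(correlation: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a signed matrix into positive and negative-magnitude channels.

    Both returned matrices are non-negative with zero diagonal, and for
    every node pair at most one of the two is nonzero.
    """
    c = np.asarray(correlation, dtype=float).copy()
    np.fill_diagonal(c, 0.0)
    positive = np.where(c > 0, c, 0.0)
    negative = np.where(c < 0, -c, 0.0)
    return positive, negative


def build_signed_networks(
    series_list: list[RegionalTimeSeries], shift_samples: int = 4
) -> SignedNetworkSet:
    """Full per-block pipeline: window, correlate, sign-split."""
    out = SignedNetworkSet()
    for series in series_list:
        for seg in extract_blocks(series, shift_samples=shift_samples):
            corr = block_correlation(seg.values)
            pos, neg = sign_split(corr)
            out.append(
                BlockNetwork(
                    subject_id=seg.subject_id,
                    task=seg.task,
                    condition=seg.condition,
                    block=seg.block,
                    positive=pos,
                    negative=neg,
                )
            )
    return out


def assemble_configuration(
    networks: SignedNetworkSet,
    task_order: list | None = None,
    condition_order: list | None = None,
    dtype=np.float64,
) -> ConfigurationMatrix:
    """Stack vectorized signed block networks into an E x T matrix.

    Columns are ordered (subject, task, condition, block, sign channel);
    tasks and conditions follow the supplied orders (sorted otherwise),
    sign channels follow ``SIGN_CHANNELS``.  Every (subject, task,
    condition, block) cell must appear exactly once.
    """
    if len(networks) == 0:
        raise ValueError("no block networks supplied")
    n_regions = networks.networks[0].positive.shape[0]
    index = edge_list(n_regions)

    seen = {}
    for net in networks:
        key = (net.subject_id, net.task, net.condition, net.block)
        if key in seen:
            raise ValueError(f"duplicate block cell {key}")
        seen[key] = net

    subjects = sorted({k[0] for k in seen})
    tasks = task_order or sorted({k[1] for k in seen})
    conditions = condition_order or sorted({k[2] for k in seen})
    blocks = sorted({k[3] for k in seen})

    missing = [
        cell
        for cell in itertools.product(subjects, tasks, conditions, blocks)
        if cell not in seen
    ]
    if missing:
        raise ValueError(f"missing block cell(s): {missing[:5]}" +
                         (" ..." if len(missing) > 5 else ""))

    columns = []
    meta_rows = []
    for subj in subjects:
        for task in tasks:
            for cond in conditions:
                for block in blocks:
                    net = seen[(subj, task, cond, block)]
                    for sign in SIGN_CHANNELS:
                        mat = net.positive if sign == "pos" else net.negative
                        columns.append(vectorize_matrix(mat))
                        meta_rows.append(
                            {"subject": subj, "task": task, "condition": cond,
                             "block": block, "sign": sign}
                        )
    weights = np.array(columns, dtype=dtype).T  # E x T
    return ConfigurationMatrix(weights=weights, edge_index=index,
                               meta=pd.DataFrame(meta_rows))


def normalize_configuration(
    config: ConfigurationMatrix,
    density: bool = True,
    edge_norm: bool = True,
) -> ConfigurationMatrix:
    """Two-step normalization of the configuration matrix.

    Step 1 (``density``) rescales every observation so its edge weights
    sum to one (equalizing density between the positive and negative
    channels).  Step 2 (``edge_norm``) rescales, within each subject,
    every edge's vector of values across that subject's observations to
    unit Euclidean length.  Edges that are identically zero within a
    subject are left at zero.
    """
    weights = np.array(config.weights, dtype=float, copy=True)
    if density:
        col_sums = weights.sum(axis=0)
        if np.any(col_sums == 0):
            bad = np.where(col_sums == 0)[0]
            raise ValueError(f"all-zero observation column(s) at {bad.tolist()}")
        weights /= col_sums[None, :]

    if edge_norm:
        subject_codes = config.meta["subject"].to_numpy()
        n_zero_edges = 0
        for subj in pd.unique(subject_codes):
            cols = np.where(subject_codes == subj)[0]
            norms = np.linalg.norm(weights[:, cols], axis=1)
            zero = norms == 0
            n_zero_edges += int(zero.sum())
            norms[zero] = 1.0
            weights[:, cols] /= norms[:, None]
        if n_zero_edges:
            warnings.warn(
                f"{n_zero_edges} zero-norm edge/subject vector(s) left at zero",
                stacklevel=2,
            )
    return replace(config, weights=weights, meta=config.meta.copy())


VALID_GROUPINGS = ("task", "condition", "fixation-vs-task", "sign-channel", "subject")


@dataclass
class EdgeStrengthSummary:
    """Per-subject group means with paired tests and a subject ANOVA."""

    grouping: str
    means: pd.DataFrame  # columns: subject, group, mean_weight
    paired_tests: pd.DataFrame  # columns: group_a, group_b, t, p, df
    anova_f: float
    anova_p: float


def summarize_edge_strength(config: ConfigurationMatrix, grouping: str) -> EdgeStrengthSummary:
    """Mean edge-weight comparisons across a column grouping.

    Groups are defined on observation columns.  For every subject and
    group the mean weight over all edges and group columns is computed;
    group pairs are compared with two-sided paired t-tests across
    subjects.  A one-way ANOVA compares per-observation mean weights
    between subjects.
    """
    if grouping not in VALID_GROUPINGS:
        raise ValueError(f"grouping must be one of {VALID_GROUPINGS}")
    meta = config.meta
    if grouping == "task":
        labels = meta["task"].to_numpy()
    elif grouping == "condition":
        labels = meta["condition"].to_numpy()
    elif grouping == "fixation-vs-task":
        labels = np.where(meta["condition"] == "fixation", "fixation", "task")
    elif grouping == "sign-channel":
        labels = meta["sign"].to_numpy()
    else:
        labels = meta["subject"].to_numpy()

    subjects = config.subjects
    groups = list(pd.unique(labels))
    col_means = config.weights.mean(axis=0)
    subject_col = meta["subject"].to_numpy()

    rows = []
    for subj in subjects:
        for grp in groups:
            mask = (subject_col == subj) & (labels == grp)
            rows.append({"subject": subj, "group": grp,
                         "mean_weight": float(col_means[mask].mean())})
    means = pd.DataFrame(rows)

    tests = []
    wide = means.pivot(index="subject", columns="group", values="mean_weight")
    for a, b in itertools.combinations(groups, 2):
        if len(wide) < 2:
            raise ValueError("paired tests need at least 2 subjects")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_rel(wide[a], wide[b])
        if np.isnan(t):  # zero-variance differences: no effect
            t, p = 0.0, 1.0
        tests.append({"group_a": a, "group_b": b, "t": float(t),
                      "p": float(p), "df": len(wide) - 1})
    paired = pd.DataFrame(tests, columns=["group_a", "group_b", "t", "p", "df"])

    per_subject = [col_means[subject_col == subj] for subj in subjects]
    if len(per_subject) >= 2:
        f, p_anova = stats.f_oneway(*per_subject)
    else:
        f, p_anova = np.nan, np.nan
    return EdgeStrengthSummary(grouping=grouping, means=means, paired_tests=paired,
                               anova_f=float(f), anova_p=float(p_anova))
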