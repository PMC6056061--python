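"""Plain-text cohort I/O and an HDF5 decomposition container."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .learning import NMFParameters, SubgraphDecomposition
from .networks import RegionalTimeSeries, SystemPartition

__all__ = [
    "write_cohort",
    "read_timeseries",
    "read_partition",
    "write_partition",
    "read_behavior",
    "save_decomposition",
    "load_decomposition",
    "export_decomposition_tsv",
]


def write_cohort(out_dir, series_list, partition=None, behavior=None) -> Path:
    """Write a cohort as TSV files: one series file per subject, a block
    annotation table, and optionally partition and behavior tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotation_rows = []
    for series in series_list:
        pd.DataFrame(series.values).to_csv(
            out / f"timeseries_{series.subject_id}.tsv", sep="\t",
            header=False, index=False)
        ann = series.annotations.copy()
        ann.insert(0, "subject", series.subject_id)
        annotation_rows.append(ann)
    pd.concat(annotation_rows, ignore_index=True).to_csv(
        out / "annotations.tsv", sep="\t", index=False)
    if partition is not None:
        write_partition(out / "partition.tsv", partition)
    if behavior is not None:
        behavior.to_csv(out / "behavior.tsv", sep="\t", index=False)
    return out


def read_timeseries(cohort_dir) -> list[RegionalTimeSeries]:
    cohort_dir = Path(cohort_dir)
    annotations = pd.read_csv(cohort_dir / "annotations.tsv", sep="\t")
    series_list = []
    for subj, ann in annotations.groupby("subject", sort=True):
        values = pd.read_csv(
            cohort_dir / f"timeseries_{subj}.tsv", sep="\t", header=None
        ).to_numpy(dtype=float)
        series_list.append(RegionalTimeSeries(
            subject_id=str(subj), values=values,
            annotations=ann.drop(columns="subject").reset_index(drop=True)))
    return series_list


def write_partition(path, partition: SystemPartition) -> None:
    pd.DataFrame({"region_id": np.arange(partition.n_regions),
                  "system_label": partition.labels}).to_csv(
        path, sep="\t", index=False)


def read_partition(path) -> SystemPartition:
    table = pd.read_csv(path, sep="\t").sort_values("region_id")
    return SystemPartition(labels=table["system_label"].to_numpy())


def read_behavior(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_decomposition(path, decomposition: SubgraphDecomposition,
                       edge_index: np.ndarray, observation_meta: pd.DataFrame,
                       extra_seeds=None) -> None:
    """Store W, H, edge index, column metadata and parameters in HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("W", data=decomposition.W)
        f.create_dataset("H", data=decomposition.H)
        f.create_dataset("objective_trace", data=decomposition.objective_trace)
        f.create_dataset("edge_index", data=np.asarray(edge_index))
        meta = f.create_group("observation_meta")
        for col in observation_meta.columns:
            values = observation_meta[col].to_numpy()
            if values.dtype.kind in "OU":
                values = values.astype("S")
            meta.create_dataset(col, data=values)
        p = decomposition.params
        f.attrs["params"] = json.dumps(
            {"m": p.m, "beta": p.beta, "alpha": p.alpha,
             "max_iter": p.max_iter, "tol": p.tol, "seed": p.seed})
        if extra_seeds is not None:
            f.create_dataset("run_seeds", data=np.asarray(extra_seeds))


def load_decomposition(path):
    """Load (decomposition, edge_index, observation_meta) from HDF5."""
    with h5py.File(path, "r") as f:
        W = f["W"][()]
        H = f["H"][()]
        trace = f["objective_trace"][()]
        edge_index = f["edge_index"][()]
        meta = {}
        for col, ds in f["observation_meta"].items():
            values = ds[()]
            if values.dtype.kind == "S":
                values = values.astype(str)
            meta[col] = values
        params = json.loads(f.attrs["params"])
    decomposition = SubgraphDecomposition(
        W=W, H=H, objective_trace=trace,
        params=NMFParameters(**params))
    return decomposition, edge_index, pd.DataFrame(meta)


def export_decomposition_tsv(out_dir, decomposition: SubgraphDecomposition,
                             edge_index: np.ndarray,
                             observation_meta: pd.DataFrame) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    w = pd.DataFrame(decomposition.W,
                     columns=[f"subgraph{k}" for k in range(decomposition.m)])
    w.insert(0, "node_i", edge_index[:, 0])
    w.insert(1, "node_j", edge_index[:, 1])
    w.to_csv(out / "subgraphs.tsv", sep="\t", index=False)
    h = observation_meta.copy()
    for k in range(decomposition.m):
        h[f"subgraph{k}"] = decomposition.H[k]
    h.to_csv(out / "expression.tsv", sep="\t", index=False)
    return out
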