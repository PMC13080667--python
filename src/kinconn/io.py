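"""Readers and writers for the pipeline's plain-text interchange formats.

Connectivity: one delimited text file per subject (N rows x N columns,
whitespace or comma separated), filename stem = subject id.
Parcellation: delimited table with node_id, label, network, hemisphere.
Behavior/covariates: delimited tables with a subject-id index column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .features import ConnectivityMatrix, EdgeTable, NETWORKS

__all__ = [
    "read_connectivity_matrix",
    "read_connectivity_dir",
    "write_connectivity_matrix",
    "load_parcellation",
    "read_table",
    "write_table",
    "write_cohort",
    "export_edge_table",
]

_FLOAT_FMT = "%.10g"


def _sniff_delimiter(path: Path) -> str | None:
    with open(path) as fh:
        first = fh.readline()
    return "," if "," in first else None  # None = any whitespace


def read_connectivity_matrix(path, modality: str, subject_id: str | None = None) -> ConnectivityMatrix:
    path = Path(path)
    values = np.loadtxt(path, delimiter=_sniff_delimiter(path))
    sid = subject_id if subject_id is not None else path.stem
    return ConnectivityMatrix(values, modality, sid)


def read_connectivity_dir(directory, modality: str) -> list[ConnectivityMatrix]:
    """All matrix files in a directory, sorted by filename (= subject id)."""
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix in (".txt", ".csv", ".tsv"))
    if not files:
        raise FileNotFoundError(f"no matrix files in {directory}")
    return [read_connectivity_matrix(p, modality) for p in files]


def write_connectivity_matrix(m: ConnectivityMatrix, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = directory / f"{m.subject_id}.txt"
    np.savetxt(out, m.values, fmt=_FLOAT_FMT)
    return out


def load_parcellation(path, one_based: bool = False) -> pd.DataFrame:
    """Parcellation table; set ``one_based`` for files with 1-based node ids
    (internally everything is 0-based)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"node_id", "label", "network", "hemisphere"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"parcellation missing columns: {sorted(missing)}")
    df = df.copy()
    if one_based:
        df["node_id"] = df["node_id"] - 1
    ids = np.sort(df["node_id"].to_numpy())
    if not np.array_equal(ids, np.arange(len(df))):
        raise ValueError("node ids must be contiguous 0..N-1")
    bad = set(df["network"]) - set(NETWORKS)
    if bad:
        raise ValueError(f"unknown network labels: {sorted(bad)}")
    return df.sort_values("node_id").reset_index(drop=True)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", index_col=0)


def write_table(df: pd.DataFrame, path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)
    return path


def write_cohort(cohort, directory) -> dict[str, Path]:
    """Persist a synthetic cohort in the same formats the pipeline reads."""
    from .synthetic import make_parcellation

    directory = Path(directory)
    conn_dir = directory / "connectivity"
    for m in cohort.connectivity:
        write_connectivity_matrix(m, conn_dir)
    n_nodes = cohort.connectivity[0].n_nodes
    paths = {
        "connectivity": conn_dir,
        "behavior": write_table(cohort.behavior, directory / "behavior.tsv"),
        "covariates": write_table(cohort.covariates, directory / "covariates.tsv"),
    }
    if n_nodes == 116:
        paths["parcellation"] = write_table(
            make_parcellation(), directory / "parcellation.tsv", index=False)
    np.savetxt(directory / "truth_active_edges.txt",
               cohort.truth.active_edges, fmt="%d")
    return paths


def export_edge_table(edges: EdgeTable, path) -> Path:
    """Subjects x edges table with one ``i_j`` column per edge."""
    return write_table(edges.to_frame(), path)
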