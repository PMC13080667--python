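"""Connectome edge features: vectorization, residualization, standardization.

Per-subject connectivity is a dense symmetric node x node matrix (structural
connectivity: nonnegative streamline-type weights with zero diagonal;
functional connectivity: correlation values in [-1, 1] with unit diagonal).
Each matrix is flattened to its strict upper triangle, giving
N*(N-1)/2 edge features per subject (6670 for the 116-node parcellation),
which are then residualized against nuisance covariates (age, sex,
education) and z-scored column-wise before dimensionality reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NETWORKS",
    "ConnectivityMatrix",
    "EdgeTable",
    "edge_index",
    "vectorize_upper_triangle",
    "reconstruct_matrix",
    "residualize_features",
    "zscore_columns",
]

#: Canonical resting-state network labels: the seven Yeo cortical systems
#: plus a subcortical catch-all for non-cortical structures.
NETWORKS = (
    "Visual",
    "Somatomotor",
    "DorsalAttention",
    "VentralAttention",
    "Limbic",
    "Frontoparietal",
    "Default",
    "Subcortical",
)

#: Relative symmetry tolerance (scaled by the largest |entry|).
SYMMETRY_RTOL = 1e-8

#: Nuisance covariates regressed out of edge features.  Group membership is
#: deliberately not included: group differences are the signal of interest.
RESIDUALIZE_COLUMNS = ("age", "sex", "education")


@dataclass
class ConnectivityMatrix:
    """A single subject's symmetric connectivity matrix.

    Parameters
    ----------
    values : (N, N) ndarray
        Symmetric weights.
    modality : {"SC", "FC"}
        Structural (nonnegative, zero diagonal) or functional
        (entries in [-1, 1], unit diagonal).
    subject_id : str
        Subject identifier, used to align with behavior/covariate tables.
    """

    values: np.ndarray
    modality: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got {self.values.shape}")
        if self.values.shape[0] < 2:
            raise ValueError("connectivity matrix needs at least 2 nodes")
        if self.modality not in ("SC", "FC"):
            raise ValueError(f"modality must be 'SC' or 'FC', got {self.modality!r}")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def validate(self) -> None:
        """Raise ValueError on symmetry or modality-range violations."""
        v = self.values
        scale = max(np.abs(v).max(), 1.0)
        dev = np.abs(v - v.T).max()
        if dev > SYMMETRY_RTOL * scale:
            raise ValueError(
                f"matrix for subject {self.subject_id!r} is asymmetric: "
                f"max |A - A.T| = {dev:.3e} (tolerance {SYMMETRY_RTOL * scale:.3e})"
            )
        if self.modality == "SC":
            if v.min() < 0:
                raise ValueError(f"SC matrix {self.subject_id!r} has negative weights")
            if np.abs(np.diag(v)).max() > SYMMETRY_RTOL * scale:
                raise ValueError(f"SC matrix {self.subject_id!r} has nonzero diagonal")
        else:
            if np.abs(v).max() > 1 + 1e-8:
                raise ValueError(f"FC matrix {self.subject_id!r} has entries outside [-1, 1]")


@dataclass
class EdgeTable:
    """Subjects x edges feature matrix with the defining edge order."""

    values: np.ndarray  # (n_subjects, E)
    edge_index: list[tuple[int, int]]
    subject_ids: list[str] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{i}_{j}" for i, j in self.edge_index]
        idx = self.subject_ids if self.subject_ids else None
        return pd.DataFrame(self.values, columns=cols, index=idx)


def edge_index(n_nodes: int) -> list[tuple[int, int]]:
    """Ordered (i, j), i < j pairs, row-major over the strict upper triangle."""
    iu = np.triu_indices(n_nodes, k=1)
    return list(zip(iu[0].tolist(), iu[1].tolist()))


def vectorize_upper_triangle(m: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Flatten the strict upper triangle of a symmetric matrix.

    Order is row-major: (0,1), (0,2), ..., (0,N-1), (1,2), ...
    A 116-node matrix yields 6670 features.
    """
    values = m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, dtype=float)
    scale = max(np.abs(values).max(), 1.0)
    dev = np.abs(values - values.T).max()
    if dev > SYMMETRY_RTOL * scale:
        raise ValueError(f"matrix asymmetric: max |A - A.T| = {dev:.3e}")
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu].copy()


def reconstruct_matrix(row: np.ndarray, n_nodes: int) -> np.ndarray:
    """Inverse of :func:`vectorize_upper_triangle`: symmetric, zero diagonal."""
    row = np.asarray(row, dtype=float).ravel()
    expected = n_nodes * (n_nodes - 1) // 2
    if row.size != expected:
        raise ValueError(f"row length {row.size} != {expected} for {n_nodes} nodes")
    out = np.zeros((n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, k=1)
    out[iu] = row
    out += out.T
    return out


def _design_matrix(covariates: pd.DataFrame, columns=RESIDUALIZE_COLUMNS) -> np.ndarray:
    missing = [c for c in columns if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariate table missing columns: {missing}")
    block = covariates.loc[:, list(columns)].to_numpy(dtype=float)
    if np.isnan(block).any():
        raise ValueError("missing values among residualization covariates")
    design = np.column_stack([np.ones(len(block)), block])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            "rank-deficient covariate design (constant or collinear covariate column)"
        )
    return design


def residualize_features(
    features: np.ndarray, covariates: pd.DataFrame, columns=RESIDUALIZE_COLUMNS
) -> np.ndarray:
    """Residualize each feature column against [1, age, sex, education] by OLS.

    Residual columns are orthogonal to every covariate (sample correlation
    ~ machine precision), so nuisance variation cannot drive later stages.
    Controls and patients are fit jointly in a single design.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D subjects x features array")
    design = _design_matrix(covariates, columns)
    n, ncov = design.shape
    if X.shape[0] != n:
        raise ValueError(f"features have {X.shape[0]} rows but covariates have {n}")
    if n <= ncov:
        raise ValueError(f"need more than {ncov} subjects to residualize, got {n}")
    beta, *_ = np.linalg.lstsq(design, X, rcond=None)
    return X - design @ beta


def zscore_columns(features: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Standardize columns to mean 0, SD 1 (denominator n - ddof)."""
    X = np.asarray(features, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    bad = np.flatnonzero(sd <= 0)
    if bad.size:
        shown = bad[:10].tolist()
        raise ValueError(f"zero-variance feature columns at indices {shown}"
                         + ("..." if bad.size > 10 else ""))
    return (X - mu) / sd
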