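"""Correlation-matrix PCA with Guttman-Kaiser retention and stability selection.

Edge features are z-scored, so PCA of the feature matrix is PCA of the
sample correlation matrix: each retained component explains at least as
much variance as one standardized original feature (eigenvalue >= 1,
Guttman-Kaiser rule).  Because edges vastly outnumber subjects, eigenpairs
are obtained from the thin SVD of the subjects x features matrix rather
than the full feature covariance.

The retained-component count is validated against sampling variation by
refitting on random subsamples (default 90% of subjects, repeated many
times) and taking the modal Kaiser count across resamples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PCModel",
    "StabilityReport",
    "fit_pca",
    "kaiser_count",
    "stability_select",
    "project",
]

_KAISER_TOL = 1e-9  # ">= 1" with protection against eigensolver round-off
_STD_TOL = 1e-6


@dataclass
class PCModel:
    loadings: np.ndarray       # (p, m) orthonormal columns, sign-fixed
    eigenvalues: np.ndarray    # (m,) nonincreasing; sum equals p
    n_components: int          # Kaiser count (floor 1)
    explained_variance_fraction: float

    @property
    def n_features(self) -> int:
        return self.loadings.shape[0]


@dataclass
class StabilityReport:
    counts_per_resample: np.ndarray
    stable_count: int
    subspace_similarity: float
    agreement_fraction: float = field(default=np.nan)


def _check_standardized(X: np.ndarray) -> None:
    sd = X.std(axis=0, ddof=1)
    worst = np.abs(sd - 1.0).max()
    if worst > _STD_TOL:
        raise ValueError(
            f"features must be standardized (column SD within {_STD_TOL} of 1); "
            f"worst deviation {worst:.3e}")


def fit_pca(features: np.ndarray) -> PCModel:
    """Eigen-decomposition of the sample correlation structure via thin SVD.

    Returns all min(n, p) components; ``n_components`` is the Kaiser count.
    Loadings columns are unit-norm with the largest-magnitude entry made
    positive (deterministic sign convention).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("features must be a 2-D array with n >= 2")
    _check_standardized(X)
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    # thin SVD: eigenvalues of X'X/(n-1) are s^2/(n-1); for p >> n only the
    # first n-1 can be nonzero but their sum still equals trace(corr) = p
    U, sval, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = sval**2 / (n - 1)
    loadings = Vt.T
    # sign convention: largest-|entry| of each loading column positive
    anchor = np.argmax(np.abs(loadings), axis=0)
    signs = np.sign(loadings[anchor, np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    loadings = loadings * signs
    k = kaiser_count(eigenvalues)
    frac = float(eigenvalues[:k].sum() / p)
    return PCModel(loadings, eigenvalues, k, frac)


def kaiser_count(eigenvalues: np.ndarray) -> int:
    """Number of eigenvalues >= 1 (Guttman-Kaiser), floored at 1.

    The floor guards degenerate inputs where no component reaches unit
    variance; it is logged as a warning because it signals data with no
    dominant structure.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size and np.any(np.diff(ev) > 1e-9):
        raise ValueError("eigenvalues must be nonincreasing")
    count = int(np.sum(ev >= 1.0 - _KAISER_TOL))
    if count == 0:
        warnings.warn("no eigenvalue >= 1; retaining 1 component (degenerate input)")
        count = 1
    return count


def _restandardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    sd[sd <= 0] = 1.0
    return (X - X.mean(axis=0)) / sd


def stability_select(
    features: np.ndarray,
    n_resamples: int = 5000,
    subsample_fraction: float = 0.9,
    seed: int = 0,
) -> StabilityReport:
    """Kaiser-count stability under subject subsampling.

    For each resample, ``subsample_fraction`` of subjects is drawn without
    replacement, columns are re-standardized within the subsample, and the
    Kaiser count recomputed.  ``stable_count`` is the modal count across
    resamples (ties broken toward the smaller count); the fraction of
    resamples agreeing with the mode is reported alongside the mean
    principal-angle cosine between each subsample's retained subspace and
    the full-sample model's.
    """
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    m = int(round(n * subsample_fraction))
    if m < 3:
        raise ValueError(f"subsample of {m} subjects is too small (need >= 3)")
    full = fit_pca(_restandardize(X))
    d = full.n_components
    L_full = full.loadings[:, :d]
    rng = np.random.default_rng(seed)
    counts = np.empty(n_resamples, dtype=int)
    sims = np.empty(n_resamples)
    for r in range(n_resamples):
        idx = rng.choice(n, size=m, replace=False)
        sub = fit_pca(_restandardize(X[idx]))
        counts[r] = sub.n_components
        dd = min(d, sub.n_components)
        # principal-angle cosines between retained subspaces
        sv = np.linalg.svd(L_full[:, :dd].T @ sub.loadings[:, :dd], compute_uv=False)
        sims[r] = float(np.mean(sv))
    binc = np.bincount(counts)
    stable = int(np.argmax(binc))  # argmax takes the smallest count on ties
    return StabilityReport(
        counts_per_resample=counts,
        stable_count=stable,
        subspace_similarity=float(np.mean(sims)),
        agreement_fraction=float(binc[stable] / n_resamples),
    )


def project(features: np.ndarray, model: PCModel, n_components: int | None = None) -> np.ndarray:
    """Project features onto the first ``n_components`` loading columns."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape} does not match loadings ({model.n_features} features)")
    k = model.n_components if n_components is None else int(n_components)
    if not (1 <= k <= model.loadings.shape[1]):
        raise ValueError(f"n_components={k} outside [1, {model.loadings.shape[1]}]")
    return X @ model.loadings[:, :k]
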