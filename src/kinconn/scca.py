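"""Elastic-net sparse canonical correlation analysis between two views.

The engine couples a brain view (principal-component scores of residualized
connectome edges) with a behavior view (nine robotic task scores) through
modes of maximal correlation, with:

* L1 sparsity per view controlled by a grid value c in [0, 1] that maps to
  an L1 bound 1 + c*(sqrt(d) - 1) on the unit-norm weight vector (c = 0
  forces one nonzero weight, c = 1 is unpenalized), plus a small ridge,
* penalty selection by k-fold cross-validated grid search over the
  11 x 11 grid {0.0, 0.1, ..., 1.0}^2 (mean held-out canonical
  correlation, ties toward sparser pairs),
* permutation inference in which behavior rows are shuffled and the
  *entire* procedure -- including penalty tuning -- is re-run per shuffle,
* successive modes via Hotelling deflation of the cross-covariance,
  stopping at the first non-significant mode,
* repeated k-fold cross-validation as an out-of-sample generalizability
  estimate.

The numerical core lives in :mod:`kinconn._solver`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._solver import (
    _corr,
    _covs,
    _cross_ops,
    _fit_modes_kernel,
    _fit_pair,
    _init_dirs,
    _standardize_train_test,
    _tune_grid,
)

__all__ = [
    "DEFAULT_GRID",
    "SCCAPenalties",
    "SCCAMode",
    "PermutationNull",
    "CVReport",
    "fit_scca",
    "tune_penalties",
    "permutation_test",
    "extract_modes",
    "repeated_cv",
]

DEFAULT_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 10)
_TOL = 1e-6
_MAXIT = 500
# looser stopping for the many fits inside cross-validated tuning; final
# fits always use the full-precision settings above
_CV_TOL = 1e-5
_CV_MAXIT = 60


@dataclass
class SCCAPenalties:
    """Per-view sparsity levels (grid values in [0, 1]) plus ridge."""

    c_brain: float
    c_behavior: float
    ridge: float = 1e-3

    def __post_init__(self) -> None:
        for name in ("c_brain", "c_behavior"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.ridge <= 0:
            raise ValueError("ridge must be > 0")


@dataclass
class SCCAMode:
    w_brain: np.ndarray
    w_behavior: np.ndarray
    variate_brain: np.ndarray
    variate_behavior: np.ndarray
    canonical_r: float
    mode_index: int
    converged: bool
    n_iter: int
    p_perm: float | None = None
    significant: bool | None = None
    penalties: SCCAPenalties | None = None


@dataclass
class PermutationNull:
    null_rs: np.ndarray
    threshold_95: float
    p_value: float
    observed_r: float
    exceeds_percentile: bool


@dataclass
class CVReport:
    test_fold_rs: np.ndarray  # folds x repeats values
    median: float
    iqr: tuple[float, float]


def _as_view(M, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError(f"{name} must be 2-D (subjects x variables)")
    if not np.all(np.isfinite(M)):
        raise ValueError(f"{name} contains non-finite values")
    return M


def _standardize(M: np.ndarray) -> np.ndarray:
    sd = M.std(axis=0, ddof=1)
    sd = np.where(sd <= 1e-12, 1.0, sd)
    return (M - M.mean(axis=0)) / sd


def _bounds(k: int, q: int, pen: SCCAPenalties) -> tuple[float, float]:
    return (1.0 + pen.c_brain * (np.sqrt(k) - 1.0),
            1.0 + pen.c_behavior * (np.sqrt(q) - 1.0))


def _orient(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip both weight vectors so the behavior weight's largest-|entry|
    is positive (leaves the canonical correlation unchanged)."""
    j = int(np.argmax(np.abs(v)))
    if v[j] < 0:
        return -u, -v
    return u, v


def fit_scca(
    X, Y, penalties: SCCAPenalties, tol: float = _TOL, max_iter: int = _MAXIT,
) -> SCCAMode:
    """Fit the leading sparse canonical mode.

    Columns of both views are standardized internally, so the fit is
    invariant to affine rescaling of any input column.  The alternating
    updates start from the leading singular vectors of the cross-covariance
    and are fully deterministic; failure to converge within ``max_iter``
    sets ``converged=False`` on the mode rather than raising.
    """
    X = _as_view(X, "X")
    Y = _as_view(Y, "Y")
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of subjects")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    Xs, Ys = _standardize(X), _standardize(Y)
    k, q = Xs.shape[1], Ys.shape[1]
    A, B, Sxy = _cross_ops(Xs, Ys, penalties.ridge)
    u0, v0 = _init_dirs(Sxy)
    bx, by = _bounds(k, q, penalties)
    u, v, conv, n_iter = _fit_pair(A, B, bx, by, u0, v0, tol, max_iter)
    u, v = _orient(u, v)
    a, b = Xs @ u, Ys @ v
    r = float(_corr(a, b))
    return SCCAMode(u, v, a, b, r, mode_index=1, converged=bool(conv),
                    n_iter=int(n_iter), penalties=penalties)


def _fold_ids(n: int, folds: int, rng: np.random.Generator) -> np.ndarray:
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if n // folds < 3:
        raise ValueError(f"{folds}-fold split of {n} subjects leaves folds < 3")
    ids = np.arange(n) % folds
    rng.shuffle(ids)
    return ids


def tune_penalties(
    X, Y, folds: int = 3, seed: int = 0, ridge: float = 1e-3,
    grid: np.ndarray | None = None, tol: float = _CV_TOL, max_iter: int = _CV_MAXIT,
) -> SCCAPenalties:
    """Cross-validated grid search over all penalty pairs.

    Every pair in the (by default 11 x 11) grid is scored by the mean
    held-out canonical correlation across folds (train weights applied to
    test subjects standardized with training statistics); ties break toward
    sparser (smaller c) pairs.  Fold assignment is deterministic in ``seed``.
    """
    X = _as_view(X, "X")
    Y = _as_view(Y, "Y")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    ids = _fold_ids(X.shape[0], folds, np.random.default_rng(seed))
    bi, bj, _, _ = _tune_grid(X, Y, ids, folds, grid, ridge, tol, max_iter)
    return SCCAPenalties(float(grid[bi]), float(grid[bj]), ridge)


def _fit_full(Xs, Ys, pen: SCCAPenalties, n_modes: int,
              tol: float = _TOL, max_iter: int = _MAXIT):
    Sxx, Syy, Sxy = _covs(Xs, Ys)
    bx, by = _bounds(Xs.shape[1], Ys.shape[1], pen)
    return _fit_modes_kernel(Sxx, Syy, Sxy, bx, by, pen.ridge, n_modes, tol, max_iter)


def permutation_test(
    X, Y, permutations: int = 5000, seed: int = 0, folds: int = 3,
    ridge: float = 1e-3, grid: np.ndarray | None = None, retune: bool = True,
    alpha: float = 0.05,
) -> PermutationNull:
    """Permutation null for the leading canonical correlation.

    Behavior rows are shuffled per permutation and the whole model --
    including the cross-validated penalty tuning when ``retune`` is on --
    is re-run, exactly as for the observed data (fold assignment held
    fixed, preserving exchangeability).  Significance is declared when the
    observed r exceeds the 95th percentile of the null; the p-value uses
    the add-one estimator (1 + #{null >= obs}) / (1 + permutations).
    """
    X = _as_view(X, "X")
    Y = _as_view(Y, "Y")
    n = X.shape[0]
    if n < 6:
        raise ValueError("need at least 6 subjects for permutation inference")
    if permutations < 19:
        raise ValueError("need >= 19 permutations to resolve alpha = 0.05")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    ids = _fold_ids(n, folds, rng)
    Xs, Ys = _standardize(X), _standardize(Y)

    def _run(Ycur):
        if retune:
            bi, bj, _, _ = _tune_grid(Xs, Ycur, ids, folds, grid, ridge,
                                      _CV_TOL, _CV_MAXIT)
            pen = SCCAPenalties(float(grid[bi]), float(grid[bj]), ridge)
        else:
            pen = SCCAPenalties(1.0, 1.0, ridge)
        U, V, _, _ = _fit_full(Xs, Ycur, pen, 1)
        return float(_corr(Xs @ U[:, 0], Ycur @ V[:, 0]))

    observed = _run(Ys)
    null_rs = np.empty(permutations)
    for p in range(permutations):
        null_rs[p] = _run(Ys[rng.permutation(n)])
    threshold = float(np.percentile(null_rs, 95))
    p_value = float((1 + np.sum(null_rs >= observed)) / (1 + permutations))
    return PermutationNull(null_rs, threshold, p_value, observed,
                           bool(observed > threshold))


def extract_modes(
    X, Y, max_modes: int = 2, seed: int = 0, permutations: int = 199,
    folds: int = 3, ridge: float = 1e-3, grid: np.ndarray | None = None,
    alpha: float = 0.05, retune: bool = True,
) -> list[SCCAMode]:
    """Sequential significant modes with per-mode permutation p-values.

    Deflation operates in subject space: after a mode is accepted, its two
    canonical variates are projected out of every column of their
    respective views, and the next mode is the leading mode of the residual
    views.  Each mode's permutation null shuffles the rows of the *current
    residual* behavior view and re-runs the whole fit (including the
    cross-validated penalty tuning when ``retune``), so observed and null
    statistics are the same functional of exchangeable data at every step.
    (Deflating the cross-covariance by earlier rank-one components while
    permuting the original data makes later modes anti-conservative: the
    observed statistic is the maximum of residual noise while the null is a
    lower order statistic of permuted noise.)

    Penalties are tuned once per step on the observed residual and reused
    across that step's permutations' final fits; each permutation retunes
    when ``retune`` is on.  Extraction stops after the first
    non-significant mode, which is still returned carrying its p-value.
    """
    X = _as_view(X, "X")
    Y = _as_view(Y, "Y")
    n = X.shape[0]
    if max_modes < 1 or max_modes > min(X.shape[1], Y.shape[1]):
        raise ValueError("max_modes must be in [1, min(k, q)]")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    ids = _fold_ids(n, folds, rng)
    Xc, Yc = _standardize(X), _standardize(Y)

    def _tuned_pen(Xcur, Ycur):
        if retune:
            bi, bj, _, _ = _tune_grid(Xcur, Ycur, ids, folds, grid, ridge,
                                      _CV_TOL, _CV_MAXIT)
            return SCCAPenalties(float(grid[bi]), float(grid[bj]), ridge)
        return SCCAPenalties(1.0, 1.0, ridge)

    def _leading(Xcur, Ycur, pen):
        U, V, conv, iters = _fit_full(Xcur, Ycur, pen, 1)
        u, v = U[:, 0], V[:, 0]
        return u, v, float(_corr(Xcur @ u, Ycur @ v)), bool(conv[0]), int(iters[0])

    def _project_out(M, variate):
        nrm2 = variate @ variate
        if nrm2 <= 1e-12:
            return M
        return M - np.outer(variate, (variate @ M) / nrm2)

    modes: list[SCCAMode] = []
    for m in range(max_modes):
        pen = _tuned_pen(Xc, Yc)
        u, v, r_obs, conv, iters = _leading(Xc, Yc, pen)
        null_rs = np.empty(permutations)
        for p in range(permutations):
            Yp = Yc[rng.permutation(n)]
            pen_p = _tuned_pen(Xc, Yp) if retune else pen
            null_rs[p] = _leading(Xc, Yp, pen_p)[2]
        pval = float((1 + np.sum(null_rs >= r_obs)) / (1 + permutations))
        u, v = _orient(u.copy(), v.copy())
        a, b = Xc @ u, Yc @ v
        mode = SCCAMode(u, v, a, b, float(_corr(a, b)), mode_index=m + 1,
                        converged=conv, n_iter=iters, p_perm=pval,
                        significant=bool(pval < alpha), penalties=pen)
        modes.append(mode)
        if not mode.significant:
            break
        Xc = _standardize(_project_out(Xc, a))
        Yc = _standardize(_project_out(Yc, b))
    return modes


def repeated_cv(
    X, Y, repeats: int = 1000, seed: int = 0, folds: int = 3,
    ridge: float = 1e-3, grid: np.ndarray | None = None,
) -> CVReport:
    """Repeated k-fold out-of-sample canonical correlation.

    Per repeat, a fresh fold split is drawn; per fold, penalties are tuned
    by inner cross-validation on the training two-thirds, the mode is fit
    on the training data, and the canonical correlation is evaluated on
    the held-out fold.  Returns all folds x repeats held-out correlations.
    """
    X = _as_view(X, "X")
    Y = _as_view(Y, "Y")
    n = X.shape[0]
    if n < 3 * folds:
        raise ValueError(f"need at least {3 * folds} subjects for {folds}-fold repeated CV")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    rs = np.empty(folds * repeats)
    pos = 0
    for _ in range(repeats):
        ids = _fold_ids(n, folds, rng)
        for f in range(folds):
            te = ids == f
            Xtr, Ytr = X[~te], Y[~te]
            Xte, Yte = X[te], Y[te]
            inner_ids = _fold_ids(len(Xtr), folds, rng)
            bi, bj, _, _ = _tune_grid(Xtr, Ytr, inner_ids, folds, grid,
                                      ridge, _CV_TOL, _CV_MAXIT)
            pen = SCCAPenalties(float(grid[bi]), float(grid[bj]), ridge)
            Xtr_s, Xte_s = _standardize_train_test(Xtr, Xte)
            Ytr_s, Yte_s = _standardize_train_test(Ytr, Yte)
            U, V, _, _ = _fit_full(Xtr_s, Ytr_s, pen, 1)
            rs[pos] = _corr(Xte_s @ U[:, 0], Yte_s @ V[:, 0])
            pos += 1
    q1, med, q3 = np.percentile(rs, [25, 50, 75])
    return CVReport(rs, float(med), (float(q1), float(q3)))
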