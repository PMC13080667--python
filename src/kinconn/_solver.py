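"""Numba kernels for the sparse CCA engine.

The estimator is an alternating ridge-regularized regression: with
standardized views X (n x k) and Y (n x q) and within/cross-view sample
covariances Sxx, Syy, Sxy, the updates are

    u <- sparsify( (Sxx + ridge*I)^-1 Sxy v )
    v <- sparsify( (Syy + ridge*I)^-1 Syx u )

where ``sparsify`` soft-thresholds to an L1 bound and renormalizes to unit
Euclidean norm.  Without sparsity (bound = sqrt(d)) and with ridge -> 0
this is power iteration on the classical CCA operator, so the unpenalized
limit coincides with the generalized-eigenvalue solution; the grid value
c in [0, 1] maps to the bound 1 + c*(sqrt(d) - 1), with c = 0 forcing a
one-hot weight vector.

Everything here is jitted because permutation inference re-runs the full
121-cell cross-validated grid search for every shuffle.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS = 1e-12


@njit(cache=True)
def _sparse_unit(x, bound):
    """Soft-threshold ``x`` so the unit-L2 result has L1 norm <= bound.

    The threshold is found by binary search; bound = 1 yields a one-hot
    vector at the largest-|x| coordinate, bound >= sqrt(len(x)) is a pure
    renormalization.
    """
    p = x.shape[0]
    out = np.zeros(p)
    nrm = 0.0
    for i in range(p):
        nrm += x[i] * x[i]
    nrm = np.sqrt(nrm)
    if nrm <= _EPS:
        out[0] = 1.0
        return out
    l1 = 0.0
    for i in range(p):
        l1 += abs(x[i])
    if l1 / nrm <= bound * (1.0 + 1e-12):
        for i in range(p):
            out[i] = x[i] / nrm
        return out
    lo = 0.0
    hi = 0.0
    for i in range(p):
        if abs(x[i]) > hi:
            hi = abs(x[i])
    for _ in range(48):
        mid = 0.5 * (lo + hi)
        s1 = 0.0
        s2 = 0.0
        for i in range(p):
            a = abs(x[i]) - mid
            if a > 0.0:
                s1 += a
                s2 += a * a
        if s2 <= 0.0:
            hi = mid
        elif s1 / np.sqrt(s2) > bound:
            lo = mid
        else:
            hi = mid
    s2 = 0.0
    for i in range(p):
        a = abs(x[i]) - hi
        if a > 0.0:
            out[i] = a if x[i] > 0.0 else -a
            s2 += a * a
    if s2 <= _EPS * _EPS:
        # threshold collapsed everything (e.g. tied maxima): one-hot fallback
        j = 0
        best = -1.0
        for i in range(p):
            if abs(x[i]) > best:
                best = abs(x[i])
                j = i
        out[:] = 0.0
        out[j] = 1.0 if x[j] >= 0.0 else -1.0
        return out
    s2 = np.sqrt(s2)
    for i in range(p):
        out[i] /= s2
    return out


@njit(cache=True)
def _delta(a, b):
    """min(||a-b||, ||a+b||): sign-insensitive change between unit vectors."""
    dm = 0.0
    dp = 0.0
    for i in range(a.shape[0]):
        dm += (a[i] - b[i]) ** 2
        dp += (a[i] + b[i]) ** 2
    return np.sqrt(min(dm, dp))


@njit(cache=True)
def _fit_pair(A, B, bx, by, u0, v0, tol, maxit):
    """Alternate u <- sparsify(A v), v <- sparsify(B u) until convergence.

    A = (Sxx+ridge I)^-1 Sxy and B = (Syy+ridge I)^-1 Syx are precomputed.
    Returns (u, v, converged, n_iter).
    """
    u = u0.copy()
    v = v0.copy()
    conv = False
    it = 0
    for it in range(maxit):
        un = _sparse_unit(A @ v, bx)
        vn = _sparse_unit(B @ un, by)
        du = _delta(un, u)
        dv = _delta(vn, v)
        u = un
        v = vn
        if du < tol and dv < tol:
            conv = True
            break
    return u, v, conv, it + 1


@njit(cache=True)
def _standardize_train_test(Xtr, Xte):
    """Standardize train columns (ddof=1) and apply train stats to test."""
    ntr = Xtr.shape[0]
    p = Xtr.shape[1]
    Xtr_s = np.empty_like(Xtr)
    Xte_s = np.empty_like(Xte)
    for j in range(p):
        mu = 0.0
        for i in range(ntr):
            mu += Xtr[i, j]
        mu /= ntr
        var = 0.0
        for i in range(ntr):
            var += (Xtr[i, j] - mu) ** 2
        sd = np.sqrt(var / (ntr - 1)) if ntr > 1 else 1.0
        if sd <= _EPS:
            sd = 1.0
        for i in range(ntr):
            Xtr_s[i, j] = (Xtr[i, j] - mu) / sd
        for i in range(Xte.shape[0]):
            Xte_s[i, j] = (Xte[i, j] - mu) / sd
    return Xtr_s, Xte_s


@njit(cache=True)
def _cross_ops(Xs, Ys, ridge):
    """Precompute A, B, Sxy for standardized views."""
    n = Xs.shape[0]
    k = Xs.shape[1]
    q = Ys.shape[1]
    Sxx = (Xs.T @ Xs) / (n - 1)
    Syy = (Ys.T @ Ys) / (n - 1)
    Sxy = (Xs.T @ Ys) / (n - 1)
    for i in range(k):
        Sxx[i, i] += ridge
    for i in range(q):
        Syy[i, i] += ridge
    A = np.linalg.solve(Sxx, Sxy)
    B = np.linalg.solve(Syy, Sxy.T)
    return A, B, Sxy


@njit(cache=True)
def _init_dirs(Sxy):
    """Leading singular vectors of the cross-covariance as warm start."""
    U, s, Vt = np.linalg.svd(Sxy)
    return U[:, 0].copy(), Vt[0, :].copy()


@njit(cache=True)
def _corr(a, b):
    n = a.shape[0]
    ma = 0.0
    mb = 0.0
    for i in range(n):
        ma += a[i]
        mb += b[i]
    ma /= n
    mb /= n
    saa = 0.0
    sbb = 0.0
    sab = 0.0
    for i in range(n):
        da = a[i] - ma
        db = b[i] - mb
        saa += da * da
        sbb += db * db
        sab += da * db
    if saa <= _EPS or sbb <= _EPS:
        return 0.0
    return sab / np.sqrt(saa * sbb)


@njit(cache=True)
def _tune_grid(X, Y, fold_ids, n_folds, grid, ridge, tol, maxit):
    """Mean held-out canonical correlation over all grid pairs.

    Returns (best_i, best_j, best_mean_r, mean_r_matrix).  The grid is
    scanned sparse-to-dense with strict-improvement replacement, so ties
    resolve toward smaller (sparser) penalty values.
    """
    n, k = X.shape
    q = Y.shape[1]
    G = grid.shape[0]
    bx_all = 1.0 + grid * (np.sqrt(k) - 1.0)
    by_all = 1.0 + grid * (np.sqrt(q) - 1.0)

    # per-fold precomputation (independent of the grid cell)
    max_te = 0
    for f in range(n_folds):
        c = 0
        for i in range(n):
            if fold_ids[i] == f:
                c += 1
        if c > max_te:
            max_te = c
    A_f = np.zeros((n_folds, k, q))
    B_f = np.zeros((n_folds, q, k))
    u0_f = np.zeros((n_folds, k))
    v0_f = np.zeros((n_folds, q))
    Xte_f = np.zeros((n_folds, max_te, k))
    Yte_f = np.zeros((n_folds, max_te, q))
    nte_f = np.zeros(n_folds, dtype=np.int64)
    for f in range(n_folds):
        nte = 0
        for i in range(n):
            if fold_ids[i] == f:
                nte += 1
        ntr = n - nte
        Xtr = np.empty((ntr, k))
        Ytr = np.empty((ntr, q))
        Xte = np.empty((nte, k))
        Yte = np.empty((nte, q))
        a = 0
        t = 0
        for i in range(n):
            if fold_ids[i] == f:
                Xte[t] = X[i]
                Yte[t] = Y[i]
                t += 1
            else:
                Xtr[a] = X[i]
                Ytr[a] = Y[i]
                a += 1
        Xtr_s, Xte_s = _standardize_train_test(Xtr, Xte)
        Ytr_s, Yte_s = _standardize_train_test(Ytr, Yte)
        A, B, Sxy = _cross_ops(Xtr_s, Ytr_s, ridge)
        u0, v0 = _init_dirs(Sxy)
        A_f[f] = A
        B_f[f] = B
        u0_f[f] = u0
        v0_f[f] = v0
        Xte_f[f, :nte] = Xte_s
        Yte_f[f, :nte] = Yte_s
        nte_f[f] = nte

    mean_r = np.empty((G, G))
    best = -1e18
    bi = 0
    bj = 0
    # warm-start continuation: within a fold, each grid cell starts from the
    # previous cell's solution (adjacent penalties give similar weights),
    # falling back to the SVD init at the start of each row
    u_w = np.empty((n_folds, k))
    v_w = np.empty((n_folds, q))
    for i in range(G):
        for f in range(n_folds):
            u_w[f] = u0_f[f]
            v_w[f] = v0_f[f]
        for j in range(G):
            tot = 0.0
            for f in range(n_folds):
                u, v, _, _ = _fit_pair(A_f[f], B_f[f], bx_all[i], by_all[j],
                                       u_w[f], v_w[f], tol, maxit)
                u_w[f] = u
                v_w[f] = v
                nte = nte_f[f]
                a = Xte_f[f, :nte] @ u
                b = Yte_f[f, :nte] @ v
                tot += _corr(a, b)
            m = tot / n_folds
            mean_r[i, j] = m
            if m > best + 1e-12:
                best = m
                bi = i
                bj = j
    return bi, bj, best, mean_r


@njit(cache=True)
def _fit_modes_kernel(Sxx, Syy, Sxy, bx, by, ridge, n_modes, tol, maxit):
    """Sequential modes by Hotelling deflation of the cross-covariance.

    After each mode, S <- S - (u'Sv) u v' removes the fitted rank-one
    component before the next alternating fit.
    """
    k = Sxy.shape[0]
    q = Sxy.shape[1]
    U = np.zeros((k, n_modes))
    V = np.zeros((q, n_modes))
    conv = np.zeros(n_modes, dtype=np.bool_)
    iters = np.zeros(n_modes, dtype=np.int64)
    Rx = Sxx.copy()
    Ry = Syy.copy()
    for i in range(k):
        Rx[i, i] += ridge
    for i in range(q):
        Ry[i, i] += ridge
    S = Sxy.copy()
    for m in range(n_modes):
        A = np.linalg.solve(Rx, S)
        B = np.linalg.solve(Ry, S.T)
        u0, v0 = _init_dirs(S)
        u, v, c, it = _fit_pair(A, B, bx, by, u0, v0, tol, maxit)
        U[:, m] = u
        V[:, m] = v
        conv[m] = c
        iters[m] = it
        scale = u @ S @ v
        S = S - scale * np.outer(u, v)
    return U, V, conv, iters


@njit(cache=True)
def _covs(Xs, Ys):
    n = Xs.shape[0]
    Sxx = (Xs.T @ Xs) / (n - 1)
    Syy = (Ys.T @ Ys) / (n - 1)
    Sxy = (Xs.T @ Ys) / (n - 1)
    return Sxx, Syy, Sxy
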