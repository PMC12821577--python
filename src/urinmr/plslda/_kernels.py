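"""Low-level PLS1-NIPALS and LDA kernels.

These are the hot path of repeated double cross-validation: a single
calibration study runs millions of train/predict cycles, so the kernels are
written in a numba-compilable subset of numpy (explicit loops, no fancy
indexing) and jitted when numba is importable.  The public API lives in
:mod:`urinmr.plslda.model`; nothing here validates its inputs.

Conventions
-----------
* ``X`` is (n_samples, n_variables) float64, C-contiguous, NOT centered —
  every kernel centers with training means internally so cross-validation
  never leaks test-set location.
* ``y01`` is an int8/int64 vector of 0/1 class labels; class 1 is the
  "positive" class (workers) and the LDA direction is oriented so class-1
  projections are larger.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by every caller
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def _solve_small(A, b):
    """Gaussian elimination with partial pivoting for tiny systems (a <= ~10)."""
    n = A.shape[0]
    M = A.copy()
    x = b.copy()
    for k in range(n):
        piv = k
        best = abs(M[k, k])
        for i in range(k + 1, n):
            if abs(M[i, k]) > best:
                best = abs(M[i, k])
                piv = i
        if piv != k:
            for j in range(n):
                tmp = M[k, j]
                M[k, j] = M[piv, j]
                M[piv, j] = tmp
            tmp = x[k]
            x[k] = x[piv]
            x[piv] = tmp
        d = M[k, k]
        if d == 0.0:
            d = 1e-300
        for i in range(k + 1, n):
            f = M[i, k] / d
            if f != 0.0:
                for j in range(k + 1, n):
                    M[i, j] -= f * M[k, j]
                x[i] -= f * x[k]
    for k in range(n - 1, -1, -1):
        s = x[k]
        for j in range(k + 1, n):
            s -= M[k, j] * x[j]
        d = M[k, k]
        if d == 0.0:
            d = 1e-300
        x[k] = s / d
    return x


@njit(cache=True, fastmath=True)
def _nipals_pls1(Xc, yc, amax):
    """NIPALS PLS1 on centered data; deflates ``Xc`` in place.

    Returns (W, P, T, q, n_used): weights, loadings, scores, inner
    regression coefficients and the number of components actually
    extracted (fewer than ``amax`` when X is exhausted).
    """
    n, p = Xc.shape
    W = np.zeros((p, amax))
    P = np.zeros((p, amax))
    T = np.zeros((n, amax))
    q = np.zeros(amax)
    used = 0
    for a in range(amax):
        w = np.dot(Xc.T, yc)
        nrm = np.sqrt(np.dot(w, w))
        if nrm < 1e-12:
            break
        w /= nrm
        t = np.dot(Xc, w)
        tt = np.dot(t, t)
        if tt < 1e-24:
            break
        pl = np.dot(Xc.T, t) / tt
        qa = np.dot(yc, t) / tt
        # rank-1 deflation of X; y is left intact (PLS1 convention)
        for i in range(n):
            ti = t[i]
            for j in range(p):
                Xc[i, j] -= ti * pl[j]
        W[:, a] = w
        P[:, a] = pl
        T[:, a] = t
        q[a] = qa
        used = a + 1
    return W, P, T, q, used


@njit(cache=True, fastmath=True)
def _test_scores(Xte_c, W, P, used):
    """Project (already train-centered) test rows onto the score space."""
    m = Xte_c.shape[0]
    Tte = np.zeros((m, used))
    Xd = Xte_c.copy()
    for a in range(used):
        t = np.dot(Xd, W[:, a])
        for i in range(m):
            ti = t[i]
            for j in range(Xd.shape[1]):
                Xd[i, j] -= ti * P[j, a]
        Tte[:, a] = t
    return Tte


@njit(cache=True, fastmath=True)
def _lda_on_scores(T, y01, a, ridge, log_prior_ratio):
    """Two-class LDA on the first ``a`` score columns.

    Returns (direction, threshold): classify class 1 when
    ``t[:a] @ direction > threshold``.
    """
    n = T.shape[0]
    mu0 = np.zeros(a)
    mu1 = np.zeros(a)
    n0 = 0
    n1 = 0
    for i in range(n):
        if y01[i] == 1:
            n1 += 1
            for j in range(a):
                mu1[j] += T[i, j]
        else:
            n0 += 1
            for j in range(a):
                mu0[j] += T[i, j]
    for j in range(a):
        mu0[j] /= n0
        mu1[j] /= n1
    S = np.zeros((a, a))
    d = np.zeros(a)
    for i in range(n):
        if y01[i] == 1:
            for j in range(a):
                d[j] = T[i, j] - mu1[j]
        else:
            for j in range(a):
                d[j] = T[i, j] - mu0[j]
        for j in range(a):
            dj = d[j]
            for k in range(j, a):
                S[j, k] += dj * d[k]
    for j in range(a):
        for k in range(j + 1, a):
            S[k, j] = S[j, k]
    denom = n - 2
    if denom < 1:
        denom = 1
    tr = 0.0
    for j in range(a):
        S[j, j] /= denom
        tr += S[j, j]
    for j in range(a):
        for k in range(a):
            if j != k:
                S[j, k] /= denom
    lam = ridge * (tr / a if tr > 0.0 else 1.0)
    for j in range(a):
        S[j, j] += lam
    diff = mu1 - mu0
    direction = _solve_small(S, diff)
    mid = 0.0
    for j in range(a):
        mid += 0.5 * (mu1[j] + mu0[j]) * direction[j]
    threshold = mid - log_prior_ratio
    return direction, threshold


@njit(cache=True, fastmath=True)
def train_predict_nested(Xtr, ytr, Xte, amax, ridge):
    """Fit PLS-LDA on (Xtr, ytr) and predict Xte for every 1..amax components.

    A single NIPALS run yields the nested sequence of score spaces; one LDA
    per component count classifies the projected test rows.  Returns an
    (n_te, amax) uint8 prediction matrix; when fewer than ``amax`` components
    are extractable the last feasible model fills the remaining columns.
    """
    n, p = Xtr.shape
    m = Xte.shape[0]
    xmean = np.zeros(p)
    for i in range(n):
        for j in range(p):
            xmean[j] += Xtr[i, j]
    for j in range(p):
        xmean[j] /= n
    Xc = np.empty((n, p))
    for i in range(n):
        for j in range(p):
            Xc[i, j] = Xtr[i, j] - xmean[j]
    n1 = 0
    for i in range(n):
        if ytr[i] == 1:
            n1 += 1
    n0 = n - n1
    ymean = n1 / n
    yc = np.empty(n)
    for i in range(n):
        yc[i] = ytr[i] - ymean
    W, P, T, q, used = _nipals_pls1(Xc, yc, amax)
    preds = np.zeros((m, amax), dtype=np.uint8)
    if used == 0:
        return preds
    Xte_c = np.empty((m, p))
    for i in range(m):
        for j in range(p):
            Xte_c[i, j] = Xte[i, j] - xmean[j]
    Tte = _test_scores(Xte_c, W, P, used)
    log_prior_ratio = np.log(n1 / n0)
    for a in range(1, amax + 1):
        aa = a if a <= used else used
        direction, threshold = _lda_on_scores(T, ytr, aa, ridge, log_prior_ratio)
        for i in range(m):
            s = 0.0
            for j in range(aa):
                s += Tte[i, j] * direction[j]
            if s > threshold:
                preds[i, a - 1] = 1
    return preds


@njit(cache=True, fastmath=True)
def train_full(X, y, a, ridge):
    """Fit a final PLS-LDA model with ``a`` components on all rows.

    Returns (xmean, W, P, T, R, direction, threshold, cv1_w, used) where
    ``R = W (P'W)^-1`` maps centered variables to scores and
    ``cv1_w = R @ direction`` is the weight of each variable along the first
    canonical variate (oriented toward class 1).
    """
    n, p = X.shape
    xmean = np.zeros(p)
    for i in range(n):
        for j in range(p):
            xmean[j] += X[i, j]
    for j in range(p):
        xmean[j] /= n
    Xc = np.empty((n, p))
    for i in range(n):
        for j in range(p):
            Xc[i, j] = X[i, j] - xmean[j]
    n1 = 0
    for i in range(n):
        if y[i] == 1:
            n1 += 1
    n0 = n - n1
    ymean = n1 / n
    yc = np.empty(n)
    for i in range(n):
        yc[i] = y[i] - ymean
    W, P, T, q, used = _nipals_pls1(Xc, yc, a)
    if used == 0:
        return (
            xmean,
            W,
            P,
            T,
            np.zeros((p, a)),
            np.zeros(a),
            0.0,
            np.zeros(p),
            0,
        )
    PtW = np.dot(P[:, :used].T, W[:, :used])
    R = np.zeros((p, used))
    # R solves (P'W)' applied column-wise: R = W (P'W)^{-1}
    ident = np.eye(used)
    PtW_inv = np.zeros((used, used))
    for j in range(used):
        PtW_inv[:, j] = _solve_small(PtW, ident[:, j].copy())
    R = np.dot(W[:, :used], PtW_inv)
    log_prior_ratio = np.log(n1 / n0)
    direction, threshold = _lda_on_scores(T, y, used, ridge, log_prior_ratio)
    cv1_w = np.dot(R, direction)
    return xmean, W, P, T, R, direction, threshold, cv1_w, used


@njit(cache=True, fastmath=True)
def predict_full(Xte, xmean, W, P, direction, threshold, used):
    """Class predictions of a fitted full model for new rows."""
    m, p = Xte.shape
    Xc = np.empty((m, p))
    for i in range(m):
        for j in range(p):
            Xc[i, j] = Xte[i, j] - xmean[j]
    Tte = _test_scores(Xc, W, P, used)
    out = np.zeros(m, dtype=np.uint8)
    for i in range(m):
        s = 0.0
        for j in range(used):
            s += Tte[i, j] * direction[j]
        if s > threshold:
            out[i] = 1
    return out
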