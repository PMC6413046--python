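"""Numba-compiled numerical kernels.

Everything here operates on plain contiguous arrays (float64 throughout,
except the BOSS sub-model kernel which also accepts float32); the public
modules wrap these in friendlier interfaces.  The PLS1 fit returns
coefficient *paths* (one column per component count) so a single fit serves
a whole component search, which is what makes leave-one-out CV and the
1000-sub-model resampling loops affordable on one CPU.
"""
from __future__ import annotations

import numpy as np
from numba import njit

_EPS = 1e-12


@njit(cache=True)
def pls1_paths(X, y, cmax):
    """NIPALS PLS1 on pre-scaled X / centered y.

    Returns B of shape (p, cmax): column c-1 holds the regression
    coefficients (scaled space) of the c-component model.  If the data run
    out of rank before cmax the remaining columns repeat the last valid
    coefficients, so downstream component searches simply plateau.
    """
    n, p = X.shape
    Xd = X.copy()
    yd = y.copy()
    B = np.zeros((p, cmax), dtype=X.dtype)
    R = np.zeros((p, cmax), dtype=X.dtype)
    P = np.zeros((p, cmax), dtype=X.dtype)
    b = np.zeros(p, dtype=X.dtype)
    for a in range(cmax):
        w = Xd.T @ yd
        nw = np.sqrt(w @ w)
        if nw < _EPS:
            for j in range(a, cmax):
                B[:, j] = b
            return B
        w = w / nw
        t = Xd @ w
        tt = t @ t
        if tt < _EPS:
            for j in range(a, cmax):
                B[:, j] = b
            return B
        pa = (Xd.T @ t) / tt
        qa = (yd @ t) / tt
        for i in range(n):
            ti = t[i]
            for j in range(p):
                Xd[i, j] -= ti * pa[j]
            yd[i] -= qa * ti
        r = w.copy()
        for j in range(a):
            proj = 0.0
            for i in range(p):
                proj += P[i, j] * w[i]
            for i in range(p):
                r[i] -= proj * R[i, j]
        R[:, a] = r
        P[:, a] = pa
        b = b + qa * r
        B[:, a] = b
    return B


@njit(cache=True)
def column_scaling(X):
    """Column means and inverse standard deviations (ddof=1).

    Columns with sd below tolerance get inv_sd = 0, i.e. they are scaled to
    zeros instead of dividing by zero.
    """
    n, p = X.shape
    mu = np.zeros(p)
    inv = np.zeros(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, j]
        m = s / n
        ss = 0.0
        for i in range(n):
            d = X[i, j] - m
            ss += d * d
        mu[j] = m
        sd = np.sqrt(ss / (n - 1)) if n > 1 else 0.0
        inv[j] = 1.0 / sd if sd > _EPS else 0.0
    return mu, inv


@njit(cache=True)
def cv_press(X, y, fold_of, n_folds, cmax, per_fold_scaling):
    """PRESS per component count for a fixed fold assignment.

    With ``per_fold_scaling`` the autoscaling (and the response mean) is
    re-estimated inside each training fold; otherwise X and y must already
    be scaled/centered globally.
    """
    n, p = X.shape
    press = np.zeros(cmax)
    Xt = np.empty((n, p))
    yt = np.empty(n)
    for f in range(n_folds):
        m = 0
        for i in range(n):
            if fold_of[i] != f:
                Xt[m] = X[i]
                yt[m] = y[i]
                m += 1
        if m < 2:
            continue
        Xtr = Xt[:m]
        ytr = yt[:m]
        if per_fold_scaling:
            mu, inv = column_scaling(Xtr)
            ym = ytr.mean()
            Xs = np.empty((m, p))
            for i in range(m):
                for j in range(p):
                    Xs[i, j] = (Xtr[i, j] - mu[j]) * inv[j]
            ys = ytr - ym
        else:
            Xs = Xtr.copy()
            ys = ytr.copy()
            mu = np.zeros(p)
            inv = np.ones(p)
            ym = 0.0
        ceff = min(cmax, m - 1, p)
        B = pls1_paths(Xs, ys, ceff)
        for i in range(n):
            if fold_of[i] == f:
                xs = (X[i] - mu) * inv
                preds = xs @ B
                for c in range(cmax):
                    d = y[i] - (ym + preds[min(c, ceff - 1)])
                    press[c] += d * d
    return press


@njit(cache=True)
def mpa_error_profile(X, y, subsets, n_components):
    """Out-of-subset prediction errors per sample.

    ``subsets`` is (n_sub, m): row s lists the sample indices included in
    sub-dataset s (duplicates allowed for bootstrap draws).  Each sub-model
    is autoscaled on its own samples, fitted with ``n_components`` PLS
    components and used to predict the excluded samples.  Returns
    (signed_error_sum, absolute_error_sum, count) per sample.
    """
    n, p = X.shape
    n_sub, m = subsets.shape
    err = np.zeros(n)
    err_abs = np.zeros(n)
    cnt = np.zeros(n)
    inset = np.zeros(n, np.bool_)
    Xt = np.empty((m, p))
    yt = np.empty(m)
    for s in range(n_sub):
        for i in range(n):
            inset[i] = False
        for j in range(m):
            k = subsets[s, j]
            inset[k] = True
            Xt[j] = X[k]
            yt[j] = y[k]
        mu, inv = column_scaling(Xt)
        ym = yt.mean()
        Xs = np.empty((m, p))
        for i in range(m):
            for j in range(p):
                Xs[i, j] = (Xt[i, j] - mu[j]) * inv[j]
        ceff = min(n_components, m - 1, p)
        B = pls1_paths(Xs, yt - ym, ceff)
        b = B[:, ceff - 1]
        for i in range(n):
            if not inset[i]:
                acc = 0.0
                for j in range(p):
                    acc += (X[i, j] - mu[j]) * inv[j] * b[j]
                pred = ym + acc
                err[i] += y[i] - pred
                err_abs[i] += abs(y[i] - pred)
                cnt[i] += 1.0
    return err, err_abs, cnt


@njit(cache=True)
def boss_submodels(Xs, yc, draws, n_components):
    """One BOSS iteration: fit a PLS sub-model per bootstrap variable draw.

    Xs/yc are globally autoscaled/centered (variable subsets share the same
    samples, so scaling commutes with column selection) and may be float32:
    the sub-models only rank variables and sub-models, they are never
    reported.  ``draws`` is (n_sub, d): row s holds a weighted bootstrap
    draw of variable indices; the distinct indices form sub-model s.
    Returns per-sub-model normalized absolute coefficients scattered to
    full width (n_sub, p) plus each sub-model's training RMSE, so the
    caller can let only the best sub-models vote on the next weights.
    """
    n, p = Xs.shape
    n_sub, d = draws.shape
    contrib = np.zeros((n_sub, p), dtype=Xs.dtype)
    rmse = np.full(n_sub, np.inf)
    idx = np.empty(d, np.int64)
    for s in range(n_sub):
        row = np.sort(draws[s])
        ln = 0
        prev = -1
        for j in range(d):
            v = row[j]
            if v != prev:
                idx[ln] = v
                ln += 1
                prev = v
        Xt = np.empty((n, ln), dtype=Xs.dtype)
        for i in range(n):
            for j in range(ln):
                Xt[i, j] = Xs[i, idx[j]]
        ceff = min(n_components, ln, n - 1)
        B = pls1_paths(Xt, yc, ceff)
        b = B[:, ceff - 1]
        tot = 0.0
        for j in range(ln):
            tot += abs(b[j])
        if tot <= 0.0:
            continue
        rss = 0.0
        for i in range(n):
            pred = 0.0
            for j in range(ln):
                pred += Xt[i, j] * b[j]
            dd = yc[i] - pred
            rss += dd * dd
        rmse[s] = np.sqrt(rss / n)
        for j in range(ln):
            contrib[s, idx[j]] = abs(b[j]) / tot
    return contrib, rmse
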