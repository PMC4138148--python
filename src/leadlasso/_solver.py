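"""Compiled group-descent path kernel.

Same algorithm as :func:`leadlasso.grouplasso.fit_group_lasso` — block
coordinate descent with the 1/4-curvature majorization and the closed-form
group soft-threshold on orthonormalized blocks, warm-started along a
decreasing lambda grid — specialized for speed with numba.  When numba is
unavailable the pure-Python fitter is used instead; both minimize the same
convex objective to the same tolerance, so solutions agree to within it.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba present in the supported env
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap


@njit(cache=False)
def _sweep(X, y, eta, beta, b0, starts, ends, thresh, active_only, active):
    """One pass: intercept MM step, then each (active) group's exact
    soft-threshold update.  Returns (new_b0, max abs coefficient change)."""
    n, _ = X.shape
    # intercept step
    s = 0.0
    for i in range(n):
        s += y[i] - 1.0 / (1.0 + np.exp(-eta[i]))
    d0 = 4.0 * s / n
    b0 += d0
    for i in range(n):
        eta[i] += d0
    dmax = abs(d0)
    G = starts.size
    for g in range(G):
        if active_only and not active[g]:
            continue
        a, b = starts[g], ends[g]
        k = b - a
        # z = beta_g + (4/n) X_g'(y - p)
        z = np.empty(k)
        for j in range(k):
            z[j] = beta[a + j]
        for i in range(n):
            r = y[i] - 1.0 / (1.0 + np.exp(-eta[i]))
            for j in range(k):
                z[j] += 4.0 * X[i, a + j] * r / n
        nz = 0.0
        for j in range(k):
            nz += z[j] * z[j]
        nz = np.sqrt(nz)
        if nz <= thresh[g]:
            shrink = 0.0
        else:
            shrink = 1.0 - thresh[g] / nz
        changed = False
        for j in range(k):
            new = shrink * z[j]
            d = new - beta[a + j]
            if d != 0.0:
                changed = True
                ad = abs(d)
                if ad > dmax:
                    dmax = ad
                for i in range(n):
                    eta[i] += X[i, a + j] * d
                beta[a + j] = new
        active[g] = False
        for j in range(k):
            if beta[a + j] != 0.0:
                active[g] = True
                break
        if not changed and shrink == 0.0:
            active[g] = False
    return b0, dmax


@njit(cache=False)
def _path_kernel(X, y, starts, ends, sqdf, lambdas, tol, max_iter, b0_init, beta_init):
    n, p = X.shape
    G = starts.size
    L = lambdas.size
    out_b0 = np.zeros(L)
    out_beta = np.zeros((L, p))
    iters = np.zeros(L, np.int64)
    conv = np.zeros(L, np.uint8)

    beta = beta_init.copy()
    b0 = b0_init
    eta = np.empty(n)
    for i in range(n):
        acc = b0
        for j in range(p):
            if beta[j] != 0.0:
                acc += X[i, j] * beta[j]
        eta[i] = acc
    active = np.zeros(G, np.bool_)
    for g in range(G):
        for j in range(starts[g], ends[g]):
            if beta[j] != 0.0:
                active[g] = True
                break

    for l in range(L):
        lam = lambdas[l]
        thresh = np.empty(G)
        for g in range(G):
            thresh[g] = 4.0 * lam * sqdf[g]
        it = 0
        done = False
        while it < max_iter:
            b0, dmax = _sweep(X, y, eta, beta, b0, starts, ends, thresh, False, active)
            it += 1
            if dmax < tol:
                done = True
                break
            while it < max_iter:
                any_active = False
                for g in range(G):
                    if active[g]:
                        any_active = True
                        break
                if not any_active:
                    break
                b0, dmax = _sweep(X, y, eta, beta, b0, starts, ends, thresh, True, active)
                it += 1
                if dmax < tol:
                    break
        out_b0[l] = b0
        for j in range(p):
            out_beta[l, j] = beta[j]
        iters[l] = it
        conv[l] = 1 if done else 0
    return out_b0, out_beta, iters, conv


def path_solutions(
    X: np.ndarray,
    y: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
    sqdf: np.ndarray,
    lambdas: np.ndarray,
    tol: float,
    max_iter: int,
    b0_init: float,
    beta_init: np.ndarray,
):
    """Warm-started standardized-scale solutions at every lambda."""
    return _path_kernel(
        np.ascontiguousarray(X, dtype=np.float64),
        np.ascontiguousarray(y, dtype=np.float64),
        starts.astype(np.int64),
        ends.astype(np.int64),
        sqdf.astype(np.float64),
        np.ascontiguousarray(lambdas, dtype=np.float64),
        float(tol),
        int(max_iter),
        float(b0_init),
        np.ascontiguousarray(beta_init, dtype=np.float64),
    )
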