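"""Compiled coordinate-descent path solver for the L1 multinomial logistic gate.

Solves, for each lambda on a decreasing grid,

    min over (b, W):  (1/N) sum_i [ logsumexp_k(b_k + x_i W_k') - sum_k T_ik (b_k + x_i W_k') ]
                      + lambda * sum_{k != ref} ||W_k||_1

with the reference class pinned at zero and intercepts unpenalized.  T holds
(possibly fractional) responsibilities with rows summing to one.  The
algorithm is the standard proximal-Newton scheme for penalized multinomial
regression: cycle over the non-reference classes, form the diagonal-weight
quadratic approximation (weights p(1-p), floored), and run coordinate descent
with residual maintenance on a working set built from the sequential strong
rule, warm-starting each lambda from the previous one; finish each lambda
with a full KKT check so the returned point is a verified stationary point of
the convex objective.

X must be Fortran-ordered so column access is contiguous.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["mn_lasso_path"]

_WEIGHT_FLOOR = 1e-6


@njit(cache=True)
def _softmax_rows(S):
    N, K = S.shape
    P = np.empty_like(S)
    for i in range(N):
        m = S[i, 0]
        for k in range(1, K):
            if S[i, k] > m:
                m = S[i, k]
        tot = 0.0
        for k in range(K):
            P[i, k] = np.exp(S[i, k] - m)
            tot += P[i, k]
        for k in range(K):
            P[i, k] /= tot
    return P


@njit(cache=True)
def _pen_objective(S, T, W, lam, ref):
    """(1/N) [sum logsumexp - sum T*S] + lam * l1(W non-ref rows)."""
    N, K = S.shape
    f = 0.0
    for i in range(N):
        m = S[i, 0]
        for k in range(1, K):
            if S[i, k] > m:
                m = S[i, k]
        tot = 0.0
        for k in range(K):
            tot += np.exp(S[i, k] - m)
            f -= T[i, k] * S[i, k]
        f += m + np.log(tot)
    f /= N
    pen = 0.0
    for k in range(W.shape[0]):
        if k == ref:
            continue
        for j in range(W.shape[1]):
            pen += abs(W[k, j])
    return f + lam * pen


@njit(cache=True)
def _grad_matrix(X, P, T):
    """(1/N) X' (P - T): K x L gradient of the smooth part wrt W."""
    N, L = X.shape
    K = T.shape[1]
    G = np.zeros((K, L))
    for j in range(L):
        for k in range(K):
            acc = 0.0
            for i in range(N):
                acc += X[i, j] * (P[i, k] - T[i, k])
            G[k, j] = acc / N
    return G


@njit(cache=True)
def _class_cd(X, w, r, Wk, work, lam, a, max_sweeps, tol):
    """Weighted-lasso coordinate sweeps for one class; returns intercept shift.

    r is the working residual (z - s); a[j] = (1/N) sum_i w_i X_ij^2 for the
    working columns; Wk is modified in place; the accumulated intercept change
    is returned.
    """
    N = X.shape[0]
    wsum = 0.0
    for i in range(N):
        wsum += w[i]
    wsum /= N
    db_total = 0.0
    for _ in range(max_sweeps):
        # convergence on the largest curvature-scaled squared step, as in the
        # standard coordinate-descent GLM solvers
        maxd = 0.0
        # unpenalized intercept
        c0 = 0.0
        for i in range(N):
            c0 += w[i] * r[i]
        db = c0 / N / wsum
        if db != 0.0:
            for i in range(N):
                r[i] -= db
            db_total += db
            e = wsum * db * db
            if e > maxd:
                maxd = e
        for jj in range(work.size):
            j = work[jj]
            aj = a[jj]
            if aj <= 0.0:
                continue
            c = 0.0
            for i in range(N):
                c += w[i] * X[i, j] * r[i]
            c = c / N + aj * Wk[j]
            if c > lam:
                new = (c - lam) / aj
            elif c < -lam:
                new = (c + lam) / aj
            else:
                new = 0.0
            d = new - Wk[j]
            if d != 0.0:
                for i in range(N):
                    r[i] -= X[i, j] * d
                Wk[j] = new
                e = aj * d * d
                if e > maxd:
                    maxd = e
        if maxd < tol:
            break
    return db_total


@njit(cache=True)
def _solve_at_lambda(X, T, lam, ref, b, W, work_mask, max_irls, max_sweeps, tol):
    """Proximal-Newton cycles over classes on the current working set."""
    N, L = X.shape
    K = T.shape[1]
    work = np.nonzero(work_mask)[0]
    S = np.empty((N, K))
    for i in range(N):
        for k in range(K):
            acc = b[k]
            for jj in range(work.size):
                j = work[jj]
                if W[k, j] != 0.0:
                    acc += X[i, j] * W[k, j]
            S[i, k] = acc
    # include any nonzero coefficient outside the working set (shouldn't
    # happen: callers always put the active set in work_mask)
    w = np.empty(N)
    r = np.empty(N)
    a = np.empty(work.size)
    for _ in range(max_irls):
        maxstep = 0.0
        for k in range(K):
            if k == ref:
                continue
            P = _softmax_rows(S)
            for i in range(N):
                pik = P[i, k]
                wi = pik * (1.0 - pik)
                if wi < _WEIGHT_FLOOR:
                    wi = _WEIGHT_FLOOR
                w[i] = wi
                r[i] = (T[i, k] - pik) / wi
            for jj in range(work.size):
                j = work[jj]
                acc = 0.0
                for i in range(N):
                    acc += w[i] * X[i, j] * X[i, j]
                a[jj] = acc / N
            Wk_before = W[k].copy()
            b_before = b[k]
            obj_before = _pen_objective(S, T, W, lam, ref)
            db = _class_cd(X, w, r, W[k], work, lam, a, max_sweeps, tol)
            b[k] += db
            # refresh scores for class k
            for i in range(N):
                acc = b[k]
                for jj in range(work.size):
                    j = work[jj]
                    if W[k, j] != 0.0:
                        acc += X[i, j] * W[k, j]
                S[i, k] = acc
            # the quadratic approximation is not a majorizer: backtrack the
            # block step until the true penalized objective does not increase
            obj_after = _pen_objective(S, T, W, lam, ref)
            halvings = 0
            while obj_after > obj_before + 1e-12 and halvings < 12:
                b[k] = 0.5 * (b[k] + b_before)
                for jj in range(work.size):
                    j = work[jj]
                    W[k, j] = 0.5 * (W[k, j] + Wk_before[j])
                for i in range(N):
                    acc = b[k]
                    for jj in range(work.size):
                        j = work[jj]
                        if W[k, j] != 0.0:
                            acc += X[i, j] * W[k, j]
                    S[i, k] = acc
                obj_after = _pen_objective(S, T, W, lam, ref)
                halvings += 1
            if obj_after > obj_before:  # give up the block step entirely
                b[k] = b_before
                for jj in range(work.size):
                    j = work[jj]
                    W[k, j] = Wk_before[j]
                for i in range(N):
                    acc = b[k]
                    for jj in range(work.size):
                        j = work[jj]
                        if W[k, j] != 0.0:
                            acc += X[i, j] * W[k, j]
                    S[i, k] = acc
                continue
            step = 0.25 * db * db
            for jj in range(work.size):
                j = work[jj]
                d = W[k, j] - Wk_before[j]
                e = a[jj] * d * d
                if e > step:
                    step = e
            if step > maxstep:
                maxstep = step
        if maxstep < tol:
            break
    return _softmax_rows(S)


@njit(cache=True)
def mn_lasso_path(
    X, T, lams, ref, b0, W0, max_irls=8, max_sweeps=100, tol=1e-7, kkt_tol=1e-6,
    dfmax=-1,
):
    """Warm-started path over a decreasing lambda grid.

    Returns (B, Ws, n_valid): intercepts (n_lam, K), coefficients
    (n_lam, K, L) on the scale of X, and the number of grid points actually
    solved — the path stops early once the support exceeds ``dfmax`` markers
    (negative: no cap), since near-saturated fits are useless for selection
    and dominate the run time.
    """
    N, L = X.shape
    K = T.shape[1]
    n_lam = lams.size
    B = np.zeros((n_lam, K))
    Ws = np.zeros((n_lam, K, L))
    b = b0.copy()
    W = W0.copy()
    S0 = np.empty((N, K))
    for i in range(N):
        for k in range(K):
            acc = b[k]
            for j in range(L):
                if W[k, j] != 0.0:
                    acc += X[i, j] * W[k, j]
            S0[i, k] = acc
    P = _softmax_rows(S0)
    G = _grad_matrix(X, P, T)
    lam_prev = lams[0]
    for t in range(n_lam):
        lam = lams[t]
        work_mask = np.zeros(L, dtype=np.bool_)
        thr = 2.0 * lam - lam_prev
        for j in range(L):
            gmax = 0.0
            nz = False
            for k in range(K):
                if k == ref:
                    continue
                g = abs(G[k, j])
                if g > gmax:
                    gmax = g
                if W[k, j] != 0.0:
                    nz = True
            if nz or gmax >= thr - 1e-12:
                work_mask[j] = True
        for _pass in range(20):
            P = _solve_at_lambda(X, T, lam, ref, b, W, work_mask, max_irls, max_sweeps, tol)
            G = _grad_matrix(X, P, T)
            added = 0
            for j in range(L):
                if work_mask[j]:
                    continue
                for k in range(K):
                    if k == ref:
                        continue
                    if abs(G[k, j]) > lam + kkt_tol:
                        work_mask[j] = True
                        added += 1
                        break
            if added == 0:
                break
        B[t] = b
        Ws[t] = W
        lam_prev = lam
        if dfmax >= 0:
            nsup = 0
            for j in range(L):
                for k in range(K):
                    if k != ref and W[k, j] != 0.0:
                        nsup += 1
                        break
            if nsup > dfmax:
                return B, Ws, t + 1
    return B, Ws, n_lam
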