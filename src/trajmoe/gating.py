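"""Sparse multinomial logistic gate over genetic concomitants.

The gate maps a patient's marker vector g_i to class probabilities through a
reference-pinned softmax, eta_k(g; omega) = exp(omega_k0 + omega_k'g) /
sum_k' exp(...), with class ``reference_class`` fixed at zero.  Fitting
maximizes the responsibility-weighted log-likelihood

    (1/N) sum_i sum_k tau_ik log eta_k(g_i; omega)  -  lambda sum_k ||omega_k||_1

with intercepts unpenalized.  Markers are standardized to unit variance
internally so the penalty treats them symmetrically; coefficients are returned
on the original scale.  The solver is an accelerated proximal-gradient method
run along a decreasing lambda path with sequential strong-rule screening and a
full KKT check, which keeps the per-lambda cost at a couple of full-gradient
evaluations even with thousands of markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .data_model import GenotypeMatrix, ModelParameters, Responsibilities

__all__ = [
    "GatingFitReport",
    "gating_probs",
    "gating_log_probs",
    "fit_sparse_multinomial",
    "select_lambda_cv",
    "debias_refit",
    "lambda_max",
]


# --------------------------------------------------------------------------
# probability evaluation
# --------------------------------------------------------------------------

def _as_matrix(geno) -> np.ndarray:
    if isinstance(geno, GenotypeMatrix):
        return geno.values
    return np.asarray(geno, dtype=float)


def gating_log_probs(geno, omega0: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Row-stable log softmax of the per-class linear scores."""
    G = _as_matrix(geno)
    omega0 = np.asarray(omega0, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if not (np.all(np.isfinite(omega0)) and np.all(np.isfinite(omega))):
        raise ValueError("gating weights must be finite")
    scores = omega0[None, :] + G @ omega.T  # (N, K)
    return scores - logsumexp(scores, axis=1, keepdims=True)


def gating_probs(geno, params: ModelParameters | None = None, *, omega0=None, omega=None) -> np.ndarray:
    """N x K gate probabilities; rows sum to one."""
    if params is not None:
        omega0, omega = params.omega0, params.omega
    return np.exp(gating_log_probs(geno, omega0, omega))


# --------------------------------------------------------------------------
# penalized fitting
# --------------------------------------------------------------------------

@dataclass
class GatingFitReport:
    """Result of a penalized (or CV-selected) gate fit, on the original scale."""

    omega0: np.ndarray
    omega: np.ndarray
    lambda_: float
    support: set[tuple[int, int]] = field(default_factory=set)
    cv_curve: tuple[np.ndarray, np.ndarray] | None = None
    converged: bool = True
    objective: float = float("nan")

    def __post_init__(self) -> None:
        nz = {(int(k), int(l)) for k, l in zip(*np.nonzero(self.omega))}
        self.support = nz
        if self.cv_curve is not None:
            grid = np.asarray(self.cv_curve[0], dtype=float)
            if grid.size > 1 and not np.all(np.diff(grid) < 0):
                raise ValueError("cv_curve lambda grid must be strictly decreasing")

    def to_dict(self) -> dict:
        return {
            "omega0": self.omega0.tolist(),
            "omega": self.omega.tolist(),
            "lambda": float(self.lambda_),
            "support": sorted([list(s) for s in self.support]),
            "cv_curve": None
            if self.cv_curve is None
            else [np.asarray(self.cv_curve[0]).tolist(), np.asarray(self.cv_curve[1]).tolist()],
        }


class _Standardizer:
    """Column standardization with constant-column dropping."""

    def __init__(self, G: np.ndarray):
        self.mean = G.mean(axis=0)
        self.sd = G.std(axis=0)
        self.keep = self.sd > 0
        self.n_total = G.shape[1]

    def transform(self, G: np.ndarray) -> np.ndarray:
        return (G[:, self.keep] - self.mean[self.keep]) / self.sd[self.keep]

    def restore(self, b_std: np.ndarray, W_std: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map standardized-scale (b, W) back to original columns (zeros for dropped)."""
        K = b_std.shape[0]
        omega = np.zeros((K, self.n_total))
        omega[:, self.keep] = W_std / self.sd[self.keep]
        omega0 = b_std - omega[:, self.keep] @ self.mean[self.keep]
        return omega0, omega


def _nll_grad(X: np.ndarray, tau: np.ndarray, b: np.ndarray, W: np.ndarray):
    """Smooth part (1/N) * [logsumexp - tau.score] and its gradient wrt (b, W).

    ``b`` and ``W`` are full K-row arrays; the caller keeps the reference row
    at zero and ignores its gradient.
    """
    N = X.shape[0]
    S = b[None, :] + X @ W.T
    lse = logsumexp(S, axis=1)
    f = (lse.sum() - float((tau * S).sum())) / N
    P = np.exp(S - lse[:, None])
    R = (P - tau) / N
    return f, R.sum(axis=0), R.T @ X, P


def _intercept_only(tau: np.ndarray, ref: int) -> np.ndarray:
    pbar = np.clip(tau.mean(axis=0), 1e-12, None)
    b = np.log(pbar) - np.log(pbar[ref])
    return b


def lambda_max(X_std: np.ndarray, tau: np.ndarray, ref: int = 0) -> float:
    """Smallest lambda that zeroes every penalized coefficient (standardized scale)."""
    N = X_std.shape[0]
    g = np.abs(X_std.T @ tau) / N  # columns mean-zero -> gradient at intercept-only
    g[:, ref] = 0.0
    return float(g.max())


def _fit_path_std(
    X,
    tau,
    lams,
    ref=0,
    tol=1e-7,
    max_iter=100,
    kkt_tol=1e-6,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
    dfmax: int = -1,
    with_objectives: bool = True,
):
    """Solve the penalized problem at each lambda (decreasing) on standardized X.

    Thin wrapper over the compiled proximal-Newton coordinate-descent path
    (sequential strong-rule screening, full KKT verification at each lambda).
    Returns (list of (b, W), penalized objectives); entries past a ``dfmax``
    support-size stop are None.
    """
    from ._solver import mn_lasso_path

    N, Ls = X.shape
    K = tau.shape[1]
    if warm is None:
        b = _intercept_only(tau, ref)
        W = np.zeros((K, Ls))
    else:
        b, W = warm[0].copy(), warm[1].copy()
    Xf = np.asfortranarray(X)
    lams_arr = np.atleast_1d(np.asarray(lams, dtype=float))
    tau = np.ascontiguousarray(tau, dtype=float)
    B, Ws, n_valid = mn_lasso_path(
        Xf, tau, lams_arr, ref, b, W, max_sweeps=max_iter, tol=tol, kkt_tol=kkt_tol,
        dfmax=dfmax,
    )
    sols: list = []
    objs: list = []
    for t in range(lams_arr.size):
        if t >= n_valid:
            sols.append(None)
            objs.append(None)
            continue
        bt, Wt = B[t], Ws[t]
        if with_objectives:
            f, _, _, _ = _nll_grad(X, tau, bt, Wt)
            objs.append(f + float(lams_arr[t]) * float(np.abs(Wt).sum()))
        else:
            objs.append(None)
        sols.append((bt, Wt))
    return sols, objs


def _fit_unpenalized_std(X, tau, ref=0, tol=1e-10, max_iter=2000):
    """Smooth (lambda = 0) fit by L-BFGS on the reference-pinned likelihood."""
    from scipy.optimize import minimize

    N, Ls = X.shape
    K = tau.shape[1]
    nonref = [k for k in range(K) if k != ref]

    def unpack(theta):
        b = np.zeros(K)
        W = np.zeros((K, Ls))
        b[nonref] = theta[: K - 1]
        W[nonref] = theta[K - 1 :].reshape(K - 1, Ls)
        return b, W

    def fun(theta):
        b, W = unpack(theta)
        f, gb, gW, _ = _nll_grad(X, tau, b, W)
        return f, np.concatenate([gb[nonref], gW[nonref].ravel()])

    x0 = np.zeros((K - 1) * (Ls + 1))
    res = minimize(fun, x0, jac=True, method="L-BFGS-B", options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-9})
    b, W = unpack(res.x)
    return b, W, float(res.fun)


def fit_sparse_multinomial(
    geno,
    tau,
    lam: float,
    *,
    reference_class: int = 0,
    path_len: int = 5,
    tol: float = 1e-10,
    max_iter: int = 1000,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
) -> GatingFitReport:
    """L1-penalized, responsibility-weighted multinomial logistic gate fit.

    Maximizes ``(1/N) sum_ik tau_ik log eta_k(g_i) - lam * sum_k ||omega_k||_1``
    with unpenalized intercepts and the reference class pinned at zero.
    Constant marker columns are dropped from the penalized problem and their
    coefficients restored as zeros.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    G = _as_matrix(geno)
    T = tau.tau if isinstance(tau, Responsibilities) else np.asarray(tau, dtype=float)
    if G.shape[0] < T.shape[1]:
        raise ValueError("need at least K patients")
    std = _Standardizer(G)
    X = std.transform(G)
    if lam == 0.0:
        b, W, f = _fit_unpenalized_std(X, T, ref=reference_class, tol=tol)
        obj = -f
    else:
        lmax = lambda_max(X, T, ref=reference_class)
        if lam >= lmax or warm is not None:
            lams = [lam]
        else:
            lams = np.geomspace(lmax, lam, path_len)
        sols, objs = _fit_path_std(
            X, T, lams, ref=reference_class, tol=tol, max_iter=max_iter, warm=warm
        )
        b, W = sols[-1]
        obj = -objs[-1]
    omega0, omega = std.restore(b, W)
    # exact zeros on the standardized scale stay exact zeros on the original
    rep = GatingFitReport(omega0=omega0, omega=omega, lambda_=float(lam), objective=obj)
    rep._warm = (b.copy(), W.copy())  # standardized-scale warm start for reuse
    return rep


def default_lambda_grid(lmax: float, size: int = 30, floor: float = 1e-3) -> np.ndarray:
    """Geometric lambda grid from lambda_max down to floor * lambda_max."""
    return np.geomspace(lmax, floor * lmax, size)


def _stratified_folds(labels: np.ndarray, n_folds: int, seed: int) -> list[np.ndarray]:
    """Deterministic stratified fold assignment over patients."""
    from sklearn.model_selection import KFold, StratifiedKFold

    _, counts = np.unique(labels, return_counts=True)
    n_eff = min(n_folds, int(counts.min()))
    rs = int(seed) % (2**31 - 1)
    if n_eff >= 2:
        if n_eff < n_folds:
            warnings.warn(
                f"smallest class has {counts.min()} members; widening folds to {n_eff}",
                RuntimeWarning,
            )
        splitter = StratifiedKFold(n_splits=n_eff, shuffle=True, random_state=rs)
        return [test for _, test in splitter.split(labels, labels)]
    warnings.warn("a class is too small to stratify; falling back to plain folds", RuntimeWarning)
    splitter = KFold(n_splits=n_folds, shuffle=True, random_state=rs)
    return [test for _, test in splitter.split(labels)]


def select_lambda_cv(
    geno,
    tau,
    n_folds: int = 5,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
    *,
    reference_class: int = 0,
    grid_size: int = 30,
    grid_floor: float = 1e-3,
    tol: float = 1e-9,
) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """Pick lambda by patient-level cross-validation.

    Folds are stratified by the responsibility argmax and deterministic given
    ``seed``.  The score of a lambda is the mean held-out weighted multinomial
    log-likelihood, (1/n_test) sum_i sum_k tau_ik log eta_k(g_i), averaged over
    folds; the maximizing lambda is returned (ties to the larger lambda).
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    G = _as_matrix(geno)
    T = tau.tau if isinstance(tau, Responsibilities) else np.asarray(tau, dtype=float)
    std_full = _Standardizer(G)
    X_full = std_full.transform(G)
    if lambda_grid is None:
        lmax = lambda_max(X_full, T, ref=reference_class)
        lambda_grid = default_lambda_grid(max(lmax, 1e-12), size=grid_size, floor=grid_floor)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("lambda grid must be nonempty")
    if lambda_grid.size == 1:
        folds = None
        scores = np.zeros(1)
        return float(lambda_grid[0]), (lambda_grid, scores)

    hard = np.argmax(T, axis=1)
    folds = _stratified_folds(hard, n_folds, seed)
    score_sum = np.zeros(lambda_grid.size)
    solved = np.full(lambda_grid.size, True)
    n_used = 0
    dfmax = max(100, G.shape[0] // 2)  # saturated fits are never CV-optimal
    for test_idx in folds:
        mask = np.ones(G.shape[0], dtype=bool)
        mask[test_idx] = False
        G_tr, T_tr = G[mask], T[mask]
        G_te, T_te = G[test_idx], T[test_idx]
        std = _Standardizer(G_tr)
        X_tr = std.transform(G_tr)
        sols, _ = _fit_path_std(
            X_tr, T_tr, lambda_grid, ref=reference_class, tol=tol,
            dfmax=dfmax, with_objectives=False,
        )
        for s, sol in enumerate(sols):
            if sol is None:
                solved[s] = False
                continue
            omega0, omega = std.restore(sol[0], sol[1])
            lp = gating_log_probs(G_te, omega0, omega)
            score_sum[s] += float((T_te * lp).sum()) / len(test_idx)
        n_used += 1
    scores = np.where(solved, score_sum / n_used, -np.inf)
    best = int(np.argmax(scores))  # argmax takes first max -> largest lambda on ties
    return float(lambda_grid[best]), (lambda_grid, scores)


# --------------------------------------------------------------------------
# post-selection debiased refit
# --------------------------------------------------------------------------

def _support_pairs(support, K: int, L: int, ref: int) -> list[tuple[int, int]]:
    pairs = []
    support = list(support)
    if support and not isinstance(support[0], (tuple, list, np.ndarray)):
        # marker indices: union semantics, free for every non-reference class
        for l in sorted(int(m) for m in support):
            for k in range(K):
                if k != ref:
                    pairs.append((k, l))
    else:
        pairs = sorted((int(k), int(l)) for k, l in support)
        for k, l in pairs:
            if k == ref:
                raise ValueError("reference-class coefficients cannot be in the support")
    return pairs


def debias_refit(
    geno,
    labels: np.ndarray,
    support,
    *,
    K: int | None = None,
    reference_class: int = 0,
    ridge_on_separation: float = 1e-3,
    max_iter: int = 100,
) -> GatingFitReport:
    """Unpenalized maximum-likelihood refit of the selected gate coefficients.

    Fits the reference-pinned multinomial logistic model by Newton's method
    with only the intercepts and the coefficients in ``support`` free
    (``support`` may be (class, marker) pairs, or marker indices — then every
    non-reference class is free for those markers).  95% Wald intervals come
    from the inverse observed information.  If the restricted problem is
    separable the fit is ridge-stabilized and flagged (``converged`` stays
    True but the report's ``wald`` attribute is False).
    """
    G = _as_matrix(geno)
    labels = np.asarray(labels, dtype=int)
    N, L = G.shape
    if K is None:
        K = int(labels.max()) + 1
    present = np.unique(labels)
    if len(present) < K:
        raise ValueError(f"labels must contain every class 0..{K-1}")
    Y = np.zeros((N, K))
    Y[np.arange(N), labels] = 1.0
    pairs = _support_pairs(support, K, L, reference_class)
    nonref = [k for k in range(K) if k != reference_class]
    d = (K - 1) + len(pairs)

    def unpack(theta):
        b = np.zeros(K)
        W = np.zeros((K, L))
        b[nonref] = theta[: K - 1]
        for j, (k, l) in enumerate(pairs):
            W[k, l] = theta[K - 1 + j]
        return b, W

    # per-parameter design column and class index, for block-wise Hessians
    C = np.column_stack([np.ones((N, K - 1))] + [G[:, l][:, None] for _, l in pairs]) \
        if pairs else np.ones((N, K - 1))
    ks = np.array(nonref + [k for k, _ in pairs])

    def nll_grad_hess(theta, ridge=0.0):
        b, W = unpack(theta)
        S = b[None, :] + G @ W.T
        lse = logsumexp(S, axis=1)
        P = np.exp(S - lse[:, None])
        nll = float(lse.sum() - (Y * S).sum()) + 0.5 * ridge * float(theta @ theta)
        R = P - Y
        g = np.array([R[:, ks[a]] @ C[:, a] for a in range(d)])
        # observed information: H[(k,l),(k',l')] = sum_i x_il x_il' p_ik (d_kk' - p_ik')
        H = np.empty((d, d))
        for k1 in nonref:
            ia = np.nonzero(ks == k1)[0]
            for k2 in nonref:
                ib = np.nonzero(ks == k2)[0]
                w = P[:, k1] * ((k1 == k2) - P[:, k2])
                H[np.ix_(ia, ib)] = C[:, ia].T @ (w[:, None] * C[:, ib])
        return nll, g + ridge * theta, H + ridge * np.eye(d)

    def newton(ridge):
        theta = np.zeros(d)
        nll, g, H = nll_grad_hess(theta, ridge)
        ok = False
        for _ in range(max_iter):
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, g, rcond=None)[0]
            t = 1.0
            for _ in range(30):
                cand = theta - t * step
                nll_c, g_c, H_c = nll_grad_hess(cand, ridge)
                if nll_c <= nll - 1e-4 * t * float(g @ step):
                    break
                t *= 0.5
            theta, nll, g, H = cand, nll_c, g_c, H_c
            if np.max(np.abs(g)) < 1e-8 * N:
                ok = True
                break
        return theta, nll, H, ok

    theta, nll, H, ok = newton(0.0)
    wald = True
    # on (quasi-)separable data the likelihood flattens and Newton "converges"
    # at absurdly large coefficients; 15 on the +/-1 genotype scale is far
    # beyond any plausible odds ratio
    if not ok or np.max(np.abs(theta)) > 15.0:
        warnings.warn(
            "restricted refit appears separable; returning a ridge-stabilized fit "
            "(Wald intervals not valid)",
            RuntimeWarning,
        )
        theta, nll, H, ok = newton(ridge_on_separation * N)
        wald = False
    b, W = unpack(theta)
    try:
        cov = np.linalg.inv(H)
        se_vec = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se_vec = np.full(d, np.nan)
        wald = False
    from scipy.stats import norm

    zq = norm.ppf(0.975)
    se0 = np.zeros(K)
    seW = np.zeros((K, L))
    for j, k in enumerate(nonref):
        se0[k] = se_vec[j]
    for j, (k, l) in enumerate(pairs):
        seW[k, l] = se_vec[K - 1 + j]
    ci = np.stack([W - zq * seW, W + zq * seW], axis=-1)
    rep = GatingFitReport(omega0=b, omega=W, lambda_=0.0, objective=-nll / N, converged=ok or not wald)
    rep.se0 = se0
    rep.se = seW
    rep.ci = ci
    rep.wald = wald
    return rep
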