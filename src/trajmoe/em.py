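"""EM / CEM inference for the sparse mixture of experts.

Each iteration alternates an E step (posterior responsibilities from the gate
prior and the expert likelihoods), an optional classification step (hard
argmax, the CEM variant used for speed and stability), and an M step (weighted
least-squares expert updates; cross-validated lambda and an L1-penalized gate
fit).  Multiple random hard-partition initializations are run and the one with
the lowest BIC is kept; the selected gate coefficients are re-estimated
without penalty at the end to remove shrinkage bias.

The monitored objective is the quantity each mode provably cannot decrease at
fixed lambda: the penalized observed-data log-likelihood for soft EM, and the
classified complete-data penalized log-likelihood for CEM.  When lambda is
re-selected by CV inside the M step, monotonicity across lambda changes is not
guaranteed (nor asserted); in practice the final objective exceeds the
initial one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

from .data_model import (
    FitResult,
    GenotypeMatrix,
    LongitudinalClinicalData,
    ModelParameters,
    Responsibilities,
    validate_aligned,
)
from .experts import (
    DegenerateClusterError,
    expert_loglik_matrix,
    update_expert_params,
)
from .gating import (
    debias_refit,
    fit_sparse_multinomial,
    gating_log_probs,
    select_lambda_cv,
)

__all__ = [
    "EMConfig",
    "e_step",
    "classify",
    "penalized_objective",
    "observed_loglik",
    "bic",
    "n_free_parameters",
    "fit",
    "fit_two_step",
    "FitError",
]


class FitError(RuntimeError):
    """Every initialization of the EM loop failed."""


@dataclass(frozen=True)
class EMConfig:
    """Configuration of the EM/CEM loop.

    ``lambda_policy`` is either the string ``"cv"`` (re-select lambda by
    cross-validation inside every M step) or a fixed float.  ``gate`` selects
    the membership model: ``"markers"`` (the integrative sparse logistic
    gate), ``"constant"`` (mixture proportions pi_k only — the first stage of
    the 2-step baseline) or ``"none"`` (K = 1).
    """

    K: int = 3
    P: int = 1
    mode: str = "cem"  # "cem" | "em"
    n_init: int = 10
    max_iter: int = 200
    tol: float = 1e-6
    lambda_policy: str | float = "cv"
    seed: int = 0
    sigma_min: float = 1e-4
    weight_floor: float = 1.0
    n_folds: int = 5
    lambda_grid_size: int = 30
    lambda_grid_floor: float = 1e-3
    gate: str = "markers"
    reference_class: int = 0
    time_scale: float | None = None  # default: cohort max |t|
    debias: bool = True

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.mode not in ("cem", "em"):
            raise ValueError("mode must be 'cem' or 'em'")
        if self.gate not in ("markers", "constant", "none"):
            raise ValueError("gate must be 'markers', 'constant' or 'none'")


# --------------------------------------------------------------------------
# single steps
# --------------------------------------------------------------------------

def _gate_log_probs(geno, params: ModelParameters) -> np.ndarray:
    G = geno.values if isinstance(geno, GenotypeMatrix) else np.asarray(geno, float)
    return gating_log_probs(G, params.omega0, params.omega)


def e_step(
    clinical: LongitudinalClinicalData, geno, params: ModelParameters
) -> Responsibilities:
    """Posterior responsibilities tau_ik, computed in log space."""
    log_post = _gate_log_probs(geno, params) + expert_loglik_matrix(clinical, params)
    bad = ~np.isfinite(log_post.max(axis=1))
    if bad.any():
        i = int(np.nonzero(bad)[0][0])
        raise FloatingPointError(
            f"all class log-posteriors are non-finite for patient "
            f"{clinical.patient_ids[i]!r}"
        )
    tau = np.exp(log_post - logsumexp(log_post, axis=1, keepdims=True))
    tau /= tau.sum(axis=1, keepdims=True)
    return Responsibilities(tau)


def classify(tau: Responsibilities) -> np.ndarray:
    """Hard argmax labels; ties broken by the lowest class index."""
    return tau.hard_labels()


def _gate_l1(geno, omega: np.ndarray) -> float:
    """L1 norm of the gate coefficients on the standardized-marker scale.

    The penalized solver standardizes markers to unit variance, so its
    effective penalty on original-scale coefficients is sum_j sd_j |omega_kj|;
    the monitored objective must use the same norm for the M step and the
    objective to agree.
    """
    G = geno.values if isinstance(geno, GenotypeMatrix) else np.asarray(geno, float)
    if G.shape[1] == 0:
        return 0.0
    sd = G.std(axis=0)
    return float((np.abs(omega) * sd[None, :]).sum())


def penalized_objective(
    clinical: LongitudinalClinicalData,
    geno,
    tau_or_labels,
    params: ModelParameters,
    lam: float,
) -> float:
    """Expected (or classified) complete-data log-likelihood minus the penalty.

    The penalty is N * lam * sum_k ||omega_k||_1 with the L1 norm taken on the
    standardized-marker scale, so the gate block of this objective is exactly
    N times the (1/N)-scaled criterion the penalized solver maximizes; the two
    therefore agree about what an M step improves.
    """
    if isinstance(tau_or_labels, Responsibilities):
        T = tau_or_labels.tau
    else:
        arr = np.asarray(tau_or_labels)
        if arr.ndim == 1:
            T = Responsibilities.from_labels(arr, params.n_clusters).tau
        else:
            T = arr
    N = clinical.n_patients
    comp = _gate_log_probs(geno, params) + expert_loglik_matrix(clinical, params)
    return float((T * comp).sum()) - N * lam * _gate_l1(geno, params.omega)


def observed_loglik(
    clinical: LongitudinalClinicalData, geno, params: ModelParameters
) -> float:
    """Observed-data log-likelihood sum_i log sum_k eta_k(g_i) f_k(y_i)."""
    log_post = _gate_log_probs(geno, params) + expert_loglik_matrix(clinical, params)
    return float(logsumexp(log_post, axis=1).sum())


def n_free_parameters(params: ModelParameters, gate: str = "markers") -> int:
    """Effective parameter count for BIC.

    K*V*(P+1) polynomial coefficients, K*V scales, K-1 gate intercepts (or
    mixture proportions for a constant gate) and — after Lasso selection —
    only the nonzero gate coefficients.
    """
    K, V, Pp1 = params.alpha.shape
    nu = K * V * Pp1 + K * V
    if K > 1:
        nu += K - 1
        if gate == "markers":
            nu += int(np.count_nonzero(params.omega))
    return nu


def bic(fit_result, clinical: LongitudinalClinicalData, gate: str = "markers") -> float:
    """-2 loglik + nu log N for a converged fit (N = number of patients)."""
    if isinstance(fit_result, FitResult):
        ll = fit_result.loglik
        nu = n_free_parameters(fit_result.params, gate)
    else:  # (loglik, params) pair
        ll, params = fit_result
        nu = n_free_parameters(params, gate)
    return -2.0 * ll + nu * np.log(clinical.n_patients)


# --------------------------------------------------------------------------
# the fitting loop
# --------------------------------------------------------------------------

def _random_partition(rng: np.random.Generator, N: int, K: int) -> np.ndarray:
    for _ in range(100):
        z = rng.integers(0, K, size=N)
        if len(np.unique(z)) == K:
            return z
    raise FitError(f"could not draw a partition of {N} patients into {K} nonempty classes")


def _constant_gate(tau: np.ndarray, ref: int) -> tuple[np.ndarray, np.ndarray]:
    pbar = np.clip(tau.mean(axis=0), 1e-12, None)
    omega0 = np.log(pbar) - np.log(pbar[ref])
    return omega0, None


def _fit_single(
    clinical: LongitudinalClinicalData,
    geno: GenotypeMatrix | None,
    config: EMConfig,
    init_id: int,
    attempt: int,
    time_scale: float,
) -> FitResult:
    N = clinical.n_patients
    K = config.K
    L = geno.n_markers if geno is not None else 0
    rng = np.random.default_rng([config.seed % (2**31), init_id, attempt, 1013])
    labels = _random_partition(rng, N, K) if K > 1 else np.zeros(N, dtype=int)
    tau = Responsibilities.from_labels(labels, K)
    ref = config.reference_class
    G_eval = geno if geno is not None else np.zeros((N, 0))
    if geno is None:
        L = 0

    trace: list[float] = []
    lam = 0.0
    warm = None
    params = None
    converged = False
    prev_obj = None
    n_iter = 0
    for it in range(config.max_iter):
        n_iter = it + 1
        alpha, sigma = update_expert_params(
            clinical,
            tau,
            config.P,
            time_scale=time_scale,
            sigma_min=config.sigma_min,
            weight_floor=config.weight_floor,
        )
        if K == 1 or config.gate == "none":
            omega0 = np.zeros(K)
            omega = np.zeros((K, L))
            lam = 0.0
        elif config.gate == "constant":
            omega0, _ = _constant_gate(tau.tau, ref)
            omega = np.zeros((K, L))
            lam = 0.0
        else:
            if config.lambda_policy == "cv":
                lam, _curve = select_lambda_cv(
                    geno,
                    tau,
                    n_folds=config.n_folds,
                    seed=(config.seed % (2**20)) * 1009 + init_id * 211 + it,
                    reference_class=ref,
                    grid_size=config.lambda_grid_size,
                    grid_floor=config.lambda_grid_floor,
                )
            else:
                lam = float(config.lambda_policy)
            rep = fit_sparse_multinomial(
                geno, tau, lam, reference_class=ref, warm=warm
            )
            omega0, omega = rep.omega0, rep.omega
            warm = getattr(rep, "_warm", None)
        params = ModelParameters(alpha, sigma, omega0, omega, ref, time_scale)

        tau_new = e_step(clinical, G_eval, params)
        new_labels = classify(tau_new)
        if config.mode == "cem" and K > 1:
            tau_next = Responsibilities.from_labels(new_labels, K)
        else:
            tau_next = tau_new

        if config.mode == "cem":
            obj = penalized_objective(clinical, G_eval, tau_next, params, lam)
        else:
            obj = observed_loglik(clinical, G_eval, params) - N * lam * _gate_l1(
                G_eval, params.omega
            )
        trace.append(obj)

        partition_fixed = config.mode == "cem" and np.array_equal(new_labels, labels)
        obj_fixed = prev_obj is not None and abs(obj - prev_obj) <= config.tol * (
            1.0 + abs(prev_obj)
        )
        labels = new_labels
        tau_final = tau_new
        tau = tau_next
        prev_obj = obj
        if partition_fixed or obj_fixed:
            converged = True
            break

    # post-selection debiased refit of the selected gate coefficients
    omega_se = omega_ci = None
    wald_valid = True
    support = {(int(k), int(l)) for k, l in zip(*np.nonzero(params.omega))}
    if config.debias and K > 1 and config.gate == "markers" and geno is not None:
        if len(np.unique(labels)) == K:
            rep = debias_refit(
                geno, labels, support or [], K=K, reference_class=ref
            )
            params = ModelParameters(
                params.alpha, params.sigma, rep.omega0, rep.omega, ref, time_scale
            )
            omega_se, omega_ci, wald_valid = rep.se, rep.ci, rep.wald
        else:
            warnings.warn(
                "a class is empty at convergence; skipping the debiased refit",
                RuntimeWarning,
            )
            wald_valid = False

    ll = observed_loglik(clinical, G_eval, params)
    result = FitResult(
        params=params,
        tau=tau_final,
        labels=classify(tau_final),
        objective_trace=trace,
        loglik=ll,
        bic=0.0,
        lambda_=lam,
        support={(int(k), int(l)) for k, l in zip(*np.nonzero(params.omega))},
        n_iter=n_iter,
        converged=converged,
        seed=config.seed,
        init_id=init_id,
    )
    result.bic = bic((ll, params), clinical, gate=config.gate)
    result.omega_se = omega_se
    result.omega_ci = omega_ci
    result.wald_valid = wald_valid
    return result


def fit(
    clinical: LongitudinalClinicalData,
    geno: GenotypeMatrix | None,
    config: EMConfig,
) -> FitResult:
    """Fit the mixture of experts with multi-start EM/CEM and BIC selection.

    Runs ``config.n_init`` seeded random hard partitions; each is iterated to
    convergence (relative objective change below ``tol``, or an unchanged CEM
    partition) and scored by BIC after the debiased refit; the lowest-BIC
    initialization is returned.  A degenerate cluster (responsibility mass
    under ``weight_floor``) restarts that initialization with a fresh seed, up
    to 3 times.
    """
    if geno is not None:
        clinical, geno = validate_aligned(clinical, geno)
    if clinical.n_patients <= config.K:
        raise ValueError("need more patients than clusters")
    if config.gate == "markers" and geno is None:
        raise ValueError("the integrative gate requires a genotype matrix")
    if config.time_scale is not None:
        time_scale = config.time_scale
    else:
        tmax = max(float(np.max(np.abs(t))) for t in clinical.times)
        time_scale = tmax if tmax > 0 else 1.0

    best: FitResult | None = None
    failures: list[str] = []
    for init_id in range(config.n_init):
        result = None
        for attempt in range(3):
            try:
                result = _fit_single(clinical, geno, config, init_id, attempt, time_scale)
                break
            except DegenerateClusterError as err:
                failures.append(f"init {init_id} attempt {attempt}: {err}")
                continue
        if result is None:
            warnings.warn(f"initialization {init_id} failed after 3 attempts", RuntimeWarning)
            continue
        if best is None or result.bic < best.bic:
            best = result
    if best is None:
        raise FitError("all initializations failed: " + "; ".join(failures[-3:]))
    return best


def fit_two_step(
    clinical: LongitudinalClinicalData,
    geno: GenotypeMatrix,
    config: EMConfig,
) -> FitResult:
    """The 2-step baseline: trajectory-only clustering, then Lasso selection.

    Stage 1 fits the mixture with constant class weights pi_k (no genetic
    information in the clustering).  Stage 2 runs CV lambda selection, the
    penalized gate fit and the debiased refit on the final hard labels.
    """
    clinical, geno = validate_aligned(clinical, geno)
    stage1_cfg = replace(config, gate="constant", debias=False)
    stage1 = fit(clinical, geno, stage1_cfg)
    if config.K == 1:
        return stage1
    tau_hard = Responsibilities.from_labels(stage1.labels, config.K)
    lam, curve = select_lambda_cv(
        geno,
        tau_hard,
        n_folds=config.n_folds,
        seed=(config.seed % (2**20)) * 1009 + 999_331,
        reference_class=config.reference_class,
        grid_size=config.lambda_grid_size,
        grid_floor=config.lambda_grid_floor,
    )
    rep = fit_sparse_multinomial(geno, tau_hard, lam, reference_class=config.reference_class)
    support = rep.support
    omega0, omega = rep.omega0, rep.omega
    omega_se = omega_ci = None
    wald_valid = True
    if config.debias and len(np.unique(stage1.labels)) == config.K:
        deb = debias_refit(
            geno, stage1.labels, support or [], K=config.K,
            reference_class=config.reference_class,
        )
        omega0, omega = deb.omega0, deb.omega
        omega_se, omega_ci, wald_valid = deb.se, deb.ci, deb.wald
    params = ModelParameters(
        stage1.params.alpha,
        stage1.params.sigma,
        omega0,
        omega,
        config.reference_class,
        stage1.params.time_scale,
    )
    ll = observed_loglik(clinical, geno, params)
    result = FitResult(
        params=params,
        tau=stage1.tau,
        labels=stage1.labels,
        objective_trace=stage1.objective_trace,
        loglik=ll,
        bic=0.0,
        lambda_=lam,
        support={(int(k), int(l)) for k, l in zip(*np.nonzero(omega))},
        n_iter=stage1.n_iter,
        converged=stage1.converged,
        seed=config.seed,
        init_id=stage1.init_id,
    )
    result.bic = bic((ll, params), clinical, gate="markers")
    result.omega_se = omega_se
    result.omega_ci = omega_ci
    result.wald_valid = wald_valid
    return result
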