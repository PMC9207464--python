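"""Per-cluster polynomial-in-time Gaussian experts.

Each cluster k models clinical variable v as a degree-P polynomial of the
(rescaled) visit time with homoscedastic Gaussian noise sigma_vk.  The M step
for this block is a responsibility-weighted least squares per (v, k) followed
by the weighted maximum-likelihood variance (no degrees-of-freedom
correction), which is the unique maximizer of the Gaussian complete-data term.
"""

from __future__ import annotations

import warnings

import numpy as np

from .data_model import LongitudinalClinicalData, ModelParameters, Responsibilities

__all__ = [
    "polynomial_design",
    "expert_loglik",
    "expert_loglik_matrix",
    "update_expert_params",
    "DegenerateClusterError",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

SIGMA_MIN_DEFAULT = 1e-4  # variance-collapse guard on the rescaled-time axis


class DegenerateClusterError(RuntimeError):
    """A cluster's total responsibility weight fell below the floor."""


def polynomial_design(times: np.ndarray, P: int) -> np.ndarray:
    """Vandermonde rows (1, t, ..., t^P) for each visit time."""
    if P < 0:
        raise ValueError("polynomial degree P must be >= 0")
    times = np.asarray(times, dtype=float).ravel()
    if not np.all(np.isfinite(times)):
        raise ValueError("visit times must be finite")
    return np.vander(times, N=P + 1, increasing=True)


def _stacked_rescaled(clinical: LongitudinalClinicalData, time_scale: float):
    t, y, idx = clinical.stacked()
    return t / time_scale, y, idx


def expert_loglik_matrix(
    clinical: LongitudinalClinicalData, params: ModelParameters
) -> np.ndarray:
    """N x K matrix of per-patient expert log-likelihood totals.

    Entry (i, k) is the sum over this patient's non-missing visit-variable
    cells of the Gaussian log-density under cluster k.  Patients whose cells
    are all missing get 0 (they inform the fit only through the gate).
    """
    t, y, idx = _stacked_rescaled(clinical, params.time_scale)
    K, V = params.sigma.shape
    X = polynomial_design(t, params.degree)  # (M, P+1)
    out = np.zeros((clinical.n_patients, K))
    finite = np.isfinite(y)
    for k in range(K):
        mu = X @ params.alpha[k].T  # (M, V)
        resid = np.where(finite, y - mu, 0.0)
        # log phi = -0.5 log(2 pi sigma^2) - r^2 / (2 sigma^2), per cell
        ll_cells = (
            -0.5 * (_LOG_2PI + 2.0 * np.log(params.sigma[k]))
            - 0.5 * (resid / params.sigma[k]) ** 2
        )
        ll_cells = np.where(finite, ll_cells, 0.0)
        out[:, k] = np.bincount(idx, weights=ll_cells.sum(axis=1), minlength=clinical.n_patients)
    return out


def expert_loglik(
    clinical: LongitudinalClinicalData, params: ModelParameters, i: int, k: int
) -> float:
    """Expert log-likelihood of patient ``i`` under cluster ``k``."""
    if not np.any(np.isfinite(clinical.values[i])):
        warnings.warn(
            f"patient {clinical.patient_ids[i]!r} has no observed clinical cells; "
            "expert log-likelihood is 0",
            RuntimeWarning,
        )
        return 0.0
    return float(expert_loglik_matrix(clinical, params)[i, k])


def update_expert_params(
    clinical: LongitudinalClinicalData,
    tau: Responsibilities,
    P: int,
    time_scale: float = 1.0,
    sigma_min: float = SIGMA_MIN_DEFAULT,
    weight_floor: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted-MLE update of (alpha, sigma) for every (cluster, variable).

    A patient's responsibility tau_ik weights each of its visit-variable cells
    equally; missing cells contribute nothing.  Returns ``alpha`` (K, V, P+1)
    on the rescaled time axis and ``sigma`` (K, V) floored at ``sigma_min``.
    """
    t, y, idx = _stacked_rescaled(clinical, time_scale)
    N, K = tau.tau.shape
    V = clinical.n_variables
    X = polynomial_design(t, P)
    finite = np.isfinite(y)
    alpha = np.zeros((K, V, P + 1))
    sigma = np.zeros((K, V))
    cell_w_base = tau.tau[idx]  # (M, K)
    for k in range(K):
        if tau.tau[:, k].sum() <= weight_floor:
            raise DegenerateClusterError(
                f"cluster {k} has total responsibility {tau.tau[:, k].sum():.3g}"
            )
        wk = cell_w_base[:, k]
        for v in range(V):
            m = finite[:, v]
            w = wk[m]
            tot = w.sum()
            if tot <= weight_floor:
                raise DegenerateClusterError(
                    f"cluster {k}, variable {v} has no weighted observations"
                )
            Xv = X[m]
            yv = y[m, v]
            sw = np.sqrt(w)
            coef, *_ = np.linalg.lstsq(Xv * sw[:, None], yv * sw, rcond=None)
            alpha[k, v] = coef
            r = yv - Xv @ coef
            sigma[k, v] = max(np.sqrt((w * r**2).sum() / tot), sigma_min)
    return alpha, sigma
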