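"""Replicate simulation studies comparing the integrative method, the 2-step
baseline, and oracle variants that plug in true parameter blocks.

Methods
-------
``integrative``
    The full method: CEM/EM with the sparse genetic gate and CV lambda.
``two_step``
    Trajectory-only clustering with constant weights, then Lasso selection on
    the final labels.
``oracle_integrative``
    One E step / classification at the true parameters (upper bound).
``semi_oracle_integrative``
    Gate fixed at the true omega; trajectory parameters estimated by EM.
``oracle_two_step``
    Trajectory parameters fixed at truth, constant weights estimated by EM.

Selection metrics (pooled sensitivity/specificity against the true active
marker set) are reported for the two estimating methods; oracle variants are
clustering-only.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .data_model import ModelParameters, Responsibilities
from .em import EMConfig, classify, e_step, fit, fit_two_step, observed_loglik
from .evaluation import adjusted_rand_index, selection_metrics
from .experts import DegenerateClusterError, update_expert_params
from .simulate import SimulationConfig, simulate_dataset

__all__ = ["METHODS", "run_benchmark", "run_k_selection_study"]

METHODS = (
    "integrative",
    "two_step",
    "oracle_integrative",
    "semi_oracle_integrative",
    "oracle_two_step",
)


def _fit_partial_oracle(clinical, G, config, true_params, fix: str):
    """EM with one block pinned to truth: ``fix`` is "gate" or "experts".

    With the gate fixed, trajectory parameters are re-estimated each M step;
    with the experts fixed, only the constant class weights move.  Multi-start
    with the best observed log-likelihood retained.
    """
    N = clinical.n_patients
    K = config.K
    best_labels, best_ll = None, -np.inf
    for init_id in range(config.n_init):
        rng = np.random.default_rng([config.seed % (2**31), init_id, 7177])
        labels = rng.integers(0, K, size=N)
        if len(np.unique(labels)) < K:
            continue
        tau = Responsibilities.from_labels(labels, K)
        params = true_params
        prev = -np.inf
        try:
            for _ in range(config.max_iter):
                if fix == "gate":
                    alpha, sigma = update_expert_params(
                        clinical, tau, config.P,
                        time_scale=true_params.time_scale,
                        sigma_min=config.sigma_min,
                        weight_floor=config.weight_floor,
                    )
                    params = ModelParameters(
                        alpha, sigma, true_params.omega0, true_params.omega,
                        true_params.reference_class, true_params.time_scale,
                    )
                    gate_input = G
                else:  # experts fixed at truth, constant weights
                    pbar = np.clip(tau.tau.mean(axis=0), 1e-12, None)
                    omega0 = np.log(pbar) - np.log(pbar[0])
                    params = ModelParameters(
                        true_params.alpha, true_params.sigma, omega0,
                        np.zeros((K, 0)), 0, true_params.time_scale,
                    )
                    gate_input = np.zeros((N, 0))
                tau_new = e_step(clinical, gate_input, params)
                new_labels = classify(tau_new)
                if config.mode == "cem":
                    tau_next = Responsibilities.from_labels(new_labels, K)
                else:
                    tau_next = tau_new
                ll = observed_loglik(clinical, gate_input, params)
                done = abs(ll - prev) <= config.tol * (1.0 + abs(prev)) or (
                    config.mode == "cem" and np.array_equal(new_labels, labels)
                )
                labels, tau, prev = new_labels, tau_next, ll
                if done:
                    break
        except DegenerateClusterError:
            continue
        if prev > best_ll:
            best_ll, best_labels = prev, labels
    if best_labels is None:
        raise RuntimeError("all oracle initializations degenerated")
    return best_labels


def run_benchmark(
    scenario: SimulationConfig,
    methods=("integrative", "two_step"),
    n_replicates: int = 25,
    seed: int = 1,
    config: EMConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run a replicate study; returns (per-replicate table, pooled summary).

    Replicate r uses dataset seed ``seed + r`` so studies with a shared base
    seed compare methods on matched datasets.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown method(s) {sorted(unknown)}; choose from {METHODS}")
    if config is None:
        config = EMConfig(K=scenario.K, P=scenario.P)
    rows = []
    selections: dict[str, list[set[int]]] = {m: [] for m in methods}
    for r in range(n_replicates):
        ds = simulate_dataset(replace(scenario, seed=(seed + r) % (2**31)))
        cfg = replace(config, K=scenario.K, P=scenario.P, seed=(seed + r) % (2**31))
        for method in methods:
            sel: set[int] | None = None
            if method == "integrative":
                res = fit(ds.clinical, ds.geno, cfg)
                labels = res.labels
                sel = {l for _, l in res.support}
            elif method == "two_step":
                res = fit_two_step(ds.clinical, ds.geno, cfg)
                labels = res.labels
                sel = {l for _, l in res.support}
            elif method == "oracle_integrative":
                tau = e_step(ds.clinical, ds.geno, ds.true_params)
                labels = classify(tau)
            elif method == "semi_oracle_integrative":
                labels = _fit_partial_oracle(
                    ds.clinical, ds.geno, cfg, ds.true_params, fix="gate"
                )
            elif method == "oracle_two_step":
                labels = _fit_partial_oracle(
                    ds.clinical, ds.geno, cfg, ds.true_params, fix="experts"
                )
            ari = adjusted_rand_index(ds.true_labels, labels)
            rows.append(
                {
                    "method": method,
                    "replicate": r,
                    "dataset_seed": seed + r,
                    "ari": ari,
                    "n_selected": np.nan if sel is None else len(sel),
                }
            )
            if sel is not None:
                selections[method].append(sel)
    table = pd.DataFrame(rows)
    pooled: dict = {"ari_mean": table.groupby("method")["ari"].mean().to_dict()}
    active = {l for _, l, _ in scenario.omega_spec}
    for method, sels in selections.items():
        if sels:
            sm = selection_metrics(active, sels, scenario.L)
            pooled[method] = {
                "sensitivity": sm.sensitivity,
                "specificity": sm.specificity,
                "selection_counts": sm.selection_counts,
            }
    return table, pooled


def run_k_selection_study(
    scenario: SimulationConfig,
    K_values=(1, 2, 3, 4),
    n_replicates: int = 20,
    seed: int = 1,
    config: EMConfig | None = None,
) -> tuple[list[int], float]:
    """BIC model selection over a K grid on simulated replicates.

    Returns (selected K per replicate, fraction of replicates picking the
    data-generating K).  Replicate r uses dataset seed ``seed + r``.
    """
    from .model_selection import select_model

    if config is None:
        config = EMConfig(P=scenario.P)
    chosen = []
    for r in range(n_replicates):
        ds = simulate_dataset(replace(scenario, seed=(seed + r) % (2**31)))
        cfg = replace(config, P=scenario.P, seed=(seed + r) % (2**31))
        best, _ = select_model(ds.clinical, ds.geno, K_values, [scenario.P], cfg)
        chosen.append(best.params.n_clusters)
    rate = float(np.mean([k == scenario.K for k in chosen]))
    return chosen, rate
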