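"""Synthetic cohorts from the generative model, for testing and benchmarking.

The generator draws, per patient: an additive-coded genotype vector (each
marker an independent Hardy-Weinberg variant with its own allele frequency),
a latent subtype from the multinomial logistic gate, visit times uniform
within per-visit day windows, and clinical scores from the subtype's
polynomial trajectory with Gaussian noise.

The default scenario emulates a Parkinson's-disease-like simulation design:
N = 396 patients, V = 4 clinical scores, K = 3 subtypes with degree-1
trajectories, three visits in the windows (10, 410), (1800, 2200) and
(3600, 4000) days, and L = 2657 markers of which 10 drive the gate (classes 2
and 3 relative to the reference class 1).  Real restricted genotypes are
replaced by independent Hardy-Weinberg markers with allele frequencies
uniform on (0.05, 0.5), and the unstated trajectory parameters by documented
"moderate separation" defaults: shared baselines, slopes separating adjacent
cluster means by about two within-cluster standard deviations at the last
visit, and noise scales that differ across clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import (
    GenotypeMatrix,
    LongitudinalClinicalData,
    ModelParameters,
)

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "default_scenario",
    "toy_scenario",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulation scenario."""

    N: int
    V: int
    K: int
    P: int
    L: int
    omega_spec: tuple[tuple[int, int, float], ...]  # (class, marker, value), 0-based
    visit_windows: tuple[tuple[float, float], ...]  # day ranges, one per visit
    alpha: np.ndarray  # (K, V, P+1) on the day scale divided by time_scale
    sigma: np.ndarray  # (K, V)
    maf_range: tuple[float, float] = (0.05, 0.5)
    omega0: tuple[float, ...] | None = None  # None -> balance classes on average
    time_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        if self.alpha.shape != (self.K, self.V, self.P + 1):
            raise ValueError("alpha must be (K, V, P+1)")
        if self.sigma.shape != (self.K, self.V):
            raise ValueError("sigma must be (K, V)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for k, l, _ in self.omega_spec:
            if not (0 <= l < self.L) or not (0 <= k < self.K):
                raise ValueError(f"omega_spec entry ({k}, {l}) out of range")
            if k == 0:
                raise ValueError("class 0 is the reference; its gate weights are 0")
        w = list(self.visit_windows)
        for lo_, hi_ in w:
            if hi_ < lo_:
                raise ValueError("visit window upper bound below lower bound")
        for a, b in zip(w[:-1], w[1:]):
            if b[0] < a[1]:
                raise ValueError("visit windows must be non-overlapping and increasing")

    @property
    def n_active(self) -> int:
        return len({l for _, l, _ in self.omega_spec})

    def omega_matrix(self) -> np.ndarray:
        W = np.zeros((self.K, self.L))
        for k, l, v in self.omega_spec:
            W[k, l] = v
        return W


@dataclass
class SimulatedDataset:
    clinical: LongitudinalClinicalData
    geno: GenotypeMatrix
    true_labels: np.ndarray
    true_params: ModelParameters
    active_support: np.ndarray  # marker indices with a nonzero gate effect

    def write(self, clinical_path, geno_path, truth_path) -> None:
        import json

        self.clinical.write_csv(clinical_path)
        self.geno.write_csv(geno_path)
        with open(truth_path, "w") as fh:
            json.dump(
                {
                    "labels": self.true_labels.tolist(),
                    "params": self.true_params.to_dict(),
                    "active_support": self.active_support.tolist(),
                },
                fh,
                indent=2,
            )


# the canonical 10-active-marker gate pattern, 0-based marker indices:
# class 2 gets +2 on markers 2,3,4 and -1 on 5,6,7; class 3 gets +2 on 5,6,7
# and -2 on 1,8,9,10 (here classes 1 and 2, markers shifted to 0-based)
_DEFAULT_OMEGA_SPEC = tuple(
    [(1, l, 2.0) for l in (1, 2, 3)]
    + [(1, l, -1.0) for l in (4, 5, 6)]
    + [(2, l, 2.0) for l in (4, 5, 6)]
    + [(2, l, -2.0) for l in (0, 7, 8, 9)]
)

_DEFAULT_WINDOWS = ((10.0, 410.0), (1800.0, 2200.0), (3600.0, 4000.0))


def _moderate_separation_trajectories(V: int, K: int, time_scale: float):
    """Documented default (alpha, sigma) on the rescaled time axis.

    All clusters share a zero baseline (patients alike at study entry);
    slopes fan out so adjacent cluster means at the last visit (t ~ 1 after
    rescaling) are about two of the middle cluster's standard deviations
    apart; the noise scale grows across clusters (1.0, 1.5, 2.0, ...), since
    subtype differences partly lie in the variances.  Alternate variables
    progress in opposite directions, like motor scores that worsen upward and
    cognitive scores that decline downward.
    """
    alpha = np.zeros((K, V, 2))
    sigma = np.empty((K, V))
    for k in range(K):
        sigma[k, :] = 1.0 + 0.5 * k
    sep = 3.0  # slope gap between adjacent clusters at t = 1
    for v in range(V):
        direction = 1.0 if v % 2 == 0 else -1.0
        for k in range(K):
            alpha[k, v, 1] = direction * sep * k
    return alpha, sigma


def default_scenario(seed: int = 0) -> SimulationConfig:
    """The benchmark design: N=396, V=4, K=3, P=1, L=2657, 10 active markers."""
    time_scale = 4000.0
    alpha, sigma = _moderate_separation_trajectories(V=4, K=3, time_scale=time_scale)
    return SimulationConfig(
        N=396,
        V=4,
        K=3,
        P=1,
        L=2657,
        omega_spec=_DEFAULT_OMEGA_SPEC,
        visit_windows=_DEFAULT_WINDOWS,
        alpha=alpha,
        sigma=sigma,
        maf_range=(0.05, 0.5),
        omega0=None,
        time_scale=time_scale,
        seed=seed,
    )


def toy_scenario(seed: int = 0, N: int = 90, L: int = 30) -> SimulationConfig:
    """A reduced scenario (defaults: 90 patients, 30 markers) for fast tests."""
    time_scale = 4000.0
    alpha, sigma = _moderate_separation_trajectories(V=2, K=2, time_scale=time_scale)
    return SimulationConfig(
        N=N,
        V=2,
        K=2,
        P=1,
        L=L,
        omega_spec=((1, 0, 2.0), (1, 1, -2.0)),
        visit_windows=_DEFAULT_WINDOWS,
        alpha=alpha,
        sigma=sigma,
        maf_range=(0.1, 0.5),
        omega0=None,
        time_scale=time_scale,
        seed=seed,
    )


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw one cohort; bit-reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed % (2**31))
    N, L, K, V = config.N, config.L, config.K, config.V

    # independent Hardy-Weinberg markers in additive {-1, 0, 1} coding
    freqs = rng.uniform(*config.maf_range, size=L)
    u = rng.random((N, L))
    p_hom_ref = (1.0 - freqs) ** 2
    p_het = 2.0 * freqs * (1.0 - freqs)
    G = np.where(u < p_hom_ref, -1.0, np.where(u < p_hom_ref + p_het, 0.0, 1.0))

    omega = config.omega_matrix()
    if config.omega0 is None:
        # balance expected class sizes: cancel the mean linear score
        omega0 = -omega @ (2.0 * freqs - 1.0)
        omega0 -= omega0[0]
    else:
        omega0 = np.asarray(config.omega0, dtype=float)

    scores = omega0[None, :] + G @ omega.T
    scores -= scores.max(axis=1, keepdims=True)
    probs = np.exp(scores)
    probs /= probs.sum(axis=1, keepdims=True)
    z = (rng.random(N)[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)

    n_visits = len(config.visit_windows)
    lows = np.array([w[0] for w in config.visit_windows])
    highs = np.array([w[1] for w in config.visit_windows])
    times = lows + rng.random((N, n_visits)) * (highs - lows)  # day scale
    t_scaled = times / config.time_scale

    eps = rng.standard_normal((N, n_visits, V))
    powers = t_scaled[:, :, None] ** np.arange(config.P + 1)[None, None, :]
    mu = np.einsum("njp,nvp->njv", powers, config.alpha[z])
    y = mu + config.sigma[z][:, None, :] * eps

    ids = [f"P{i + 1:04d}" for i in range(N)]
    clinical = LongitudinalClinicalData(
        patient_ids=ids,
        times=[times[i] for i in range(N)],
        values=[y[i] for i in range(N)],
        variable_names=[f"score_{v + 1}" for v in range(V)],
    )
    geno = GenotypeMatrix(G, [f"m{l + 1}" for l in range(L)], ids)
    true_params = ModelParameters(
        alpha=config.alpha,
        sigma=config.sigma,
        omega0=omega0,
        omega=omega,
        reference_class=0,
        time_scale=config.time_scale,
    )
    active = np.array(sorted({l for _, l, _ in config.omega_spec}), dtype=int)
    return SimulatedDataset(clinical, geno, z.astype(int), true_params, active)
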