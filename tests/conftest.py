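import numpy as np
import pytest

import trajmoe as tm


@pytest.fixture(scope="session")
def toy_ds():
    """A small 2-cluster, 2-marker-signal cohort shared across tests."""
    return tm.simulate_dataset(tm.toy_scenario(seed=3))


@pytest.fixture(scope="session")
def strong_ds():
    """Very well separated 2-cluster toy: trajectory means ~10 sd apart."""
    import dataclasses

    base = tm.toy_scenario(seed=11, N=100, L=12)
    alpha = np.array(base.alpha, copy=True)
    alpha[1, :, 1] = [15.0, -15.0]  # slope gap ~10 within-cluster sd at t=1
    sigma = np.ones((2, 2))
    cfg = dataclasses.replace(base, alpha=alpha, sigma=sigma, omega_spec=((1, 0, 3.0),))
    return tm.simulate_dataset(cfg)


def random_soft_instance(seed, N=40, L=4, K=3, V=2, n_visits=3):
    """A random clinical + genotype + soft-responsibility instance."""
    rng = np.random.default_rng(seed)
    times = [np.sort(rng.uniform(0, 1, n_visits)) for _ in range(N)]
    values = [rng.normal(size=(n_visits, V)) for _ in range(N)]
    clinical = tm.LongitudinalClinicalData(
        [f"p{i}" for i in range(N)], times, values, [f"v{j}" for j in range(V)]
    )
    G = rng.integers(-1, 2, size=(N, L)).astype(float)
    geno = tm.GenotypeMatrix(G, [f"m{j}" for j in range(L)], clinical.patient_ids)
    tau = rng.dirichlet(np.ones(K), size=N)
    return clinical, geno, tm.Responsibilities(tau)
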