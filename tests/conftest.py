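import numpy as np
import pandas as pd
import pytest

from plaquenet.simulate import (
    SimulationConfig,
    make_hex_grid,
    simulate_amyloid_binaries,
    simulate_sample,
)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def default_sample(default_config):
    return simulate_sample(default_config)


@pytest.fixture(scope="session")
def small_grid():
    cfg = SimulationConfig(seed=0, n_rows=6, n_cols=6, region_layout=("L1", "WM"))
    return make_hex_grid(cfg, sample_id="S1")


@pytest.fixture(scope="session")
def small_binaries(small_grid):
    cfg = SimulationConfig(
        seed=3, n_rows=6, n_cols=6, region_layout=("L1", "WM"),
        n_amyloid_centers=2, binaries_per_center=10,
    )
    return simulate_amyloid_binaries(small_grid, cfg, seed=3)


def brute_force_gi_star(x, neighbors):
    """Independent Gi* oracle: literal per-spot evaluation of the formula.

    ``neighbors`` maps spot index -> iterable of neighbor indices
    (excluding self; self-weight added here).
    """
    x = np.asarray(x, float)
    n = len(x)
    xbar = x.mean()
    s = np.sqrt(np.sum(x**2) / n - xbar**2)
    out = np.empty(n)
    for i in range(n):
        w = np.zeros(n)
        for j in neighbors[i]:
            w[j] = 1.0
        w[i] = 1.0
        wi = w.sum()
        num = np.sum(w * x) - xbar * wi
        den = s * np.sqrt((n * np.sum(w**2) - wi**2) / (n - 1))
        out[i] = num / den
    return out


def brute_force_tom(adj):
    """Triple-loop topological overlap oracle."""
    a = np.asarray(adj, float).copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


@pytest.fixture(scope="session")
def gi_star_oracle():
    return brute_force_gi_star


@pytest.fixture(scope="session")
def tom_oracle():
    return brute_force_tom
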