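import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from diallelkit.core import CrossMeansMatrix, DiallelDesign
from diallelkit.simulate import SimulationSpec, default_design, simulate_diallel

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design4() -> DiallelDesign:
    """Melon-sized method-4 design: 8 parents, 3 blocks, 6 environments."""
    return default_design(method="method4")


@pytest.fixture(scope="session")
def design2() -> DiallelDesign:
    return default_design(method="method2")


@pytest.fixture(scope="session")
def design2_single() -> DiallelDesign:
    return default_design(method="method2", n_envs=1)


@pytest.fixture(scope="session")
def noisy_trial4(design4):
    """One stochastic method-4 trial at the default variance components."""
    return simulate_diallel(SimulationSpec(design=design4, seed=42))


@pytest.fixture(scope="session")
def clean_trial4():
    """Noise-free single-environment method-4 trial (genetic signal only)."""
    d = default_design(method="method4", n_envs=1)
    spec = SimulationSpec(design=d, sigma2_gE=0.0, sigma2_sE=0.0,
                          sigma2_e=0.0, sigma2_block=0.0, seed=11)
    records, truth = simulate_diallel(spec)
    return d, records, truth


def random_cross_matrix(p: int, seed: int, method: str = "method4") -> CrossMeansMatrix:
    """Random symmetric entry-mean table for oracle comparisons."""
    rng = np.random.default_rng(seed)
    arr = rng.normal(10.0, 2.0, (p, p))
    arr = (arr + arr.T) / 2.0
    if method == "method4":
        np.fill_diagonal(arr, np.nan)
    labels = [f"P{i + 1}" for i in range(p)]
    return CrossMeansMatrix(
        values=pd.DataFrame(arr, index=labels, columns=labels), method=method
    )


def constrained_ls_effects(x: CrossMeansMatrix):
    """Independent least-squares oracle for the Griffing decomposition.

    Fits x_ij = m + g_i + g_j (diagonal m + 2 g_i) by OLS over the observed
    cells with sum(g) = 0, and returns (m, g, s = residuals).
    """
    arr = x.values.to_numpy(dtype=float)
    p = len(arr)
    if x.method == "method4":
        cells = [(i, j) for i in range(p) for j in range(i + 1, p)]
    else:
        cells = [(i, j) for i in range(p) for j in range(i, p)]
    y = np.array([arr[i, j] for i, j in cells])
    X = np.zeros((len(cells), 1 + p))
    for k, (i, j) in enumerate(cells):
        X[k, 0] = 1.0
        X[k, 1 + i] += 1.0
        X[k, 1 + j] += 1.0
    # absorb sum-to-zero: g_p = -(g_1 + ... + g_{p-1})
    Z = np.column_stack([X[:, 0], X[:, 1:p] - X[:, [p]]])
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    m = beta[0]
    g = np.append(beta[1:], -beta[1:].sum())
    fit = m + g[:, None] + g[None, :]
    s = arr - fit
    if x.method == "method4":
        np.fill_diagonal(s, np.nan)
    return m, g, s
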