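import numpy as np
import pytest

from synred.gradient import WindowSpec, window_matrices
from synred.synthetic import HopfConfig, StudySpec, generate_study


def ar1_series(phi: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """AR(1) with unit marginal variance: x_t = phi x_{t-1} + sqrt(1-phi^2) e_t."""
    x = np.empty(n)
    e = rng.standard_normal(n)
    x[0] = e[0]
    s = np.sqrt(1.0 - phi**2)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + s * e[t]
    return x


def random_pd_cov(rng: np.random.Generator, dim: int = 4) -> np.ndarray:
    a = rng.standard_normal((dim, dim))
    return a @ a.T + 0.1 * np.eye(dim)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """One-subject Hopf study (control + one perturbed condition), 40 regions.

    Shared across coupling/topology/pipeline tests to amortize the cost of
    simulation and windowed decomposition.
    """
    base = HopfConfig(n_regions=40, n_samples=800)
    spec = StudySpec(
        n_subjects=1,
        n_runs=3,
        conditions=("control", "stim"),
        targets={"stim": [0, 4, 8, 12, 16]},
    )
    runs, sc = generate_study(base, spec, seed=7)
    per_cond = {"control": [], "stim": []}
    for (s, c, r), data in runs.items():
        per_cond[c].append(window_matrices(data, WindowSpec()))
    return {"runs": runs, "sc": sc, "per_cond": per_cond, "targets": [0, 4, 8, 12, 16]}
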