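"""Shared fixtures: reference systems and independent brute-force oracles."""

import numpy as np
import pytest

import fepaudit as fa


@pytest.fixture(scope="session")
def fig5a_partition() -> fa.Partition:
    """Partition of the reference configuration: n_y = n_x = 2, n_a = n_s = 1."""
    return fa.Partition(ny=2, ns=1, na=1, nx=2)


@pytest.fixture(scope="session")
def fig5a_system(fig5a_partition) -> fa.PartitionedLinearSystem:
    """Symmetric-chain system with couplings +/-0.1 and noise sigma = 0.1."""
    return fa.generate_random_system(
        "symmetric_chain", fig5a_partition, epsilon=0.1, sigma=0.1, seed=42
    )


@pytest.fixture(scope="session")
def fig5a_density(fig5a_system) -> fa.StationaryDensity:
    return fa.solve_stationary(fig5a_system)


@pytest.fixture(scope="session")
def fig5a_moments(fig5a_density, fig5a_partition) -> fa.ConditionalMoments:
    return fa.conditional_moments(fig5a_density, fig5a_partition)


def kron_lyapunov_solve(J: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Brute-force oracle: solve J Sigma + Sigma J^T = -2 Gamma by Kronecker
    vectorization (O(n^6); independent of the library solver)."""
    n = J.shape[0]
    A = np.kron(np.eye(n), J) + np.kron(J, np.eye(n))
    sigma_vec = np.linalg.solve(A, (-2.0 * gamma).reshape(-1))
    return sigma_vec.reshape(n, n)


def random_stable_system(rng: np.random.Generator, n_max: int = 12):
    """A random Hurwitz system with random partition, couplings and noise."""
    while True:
        sizes = rng.integers(0, 4, size=4)
        p_try = sizes.sum()
        if 2 <= p_try <= n_max:
            break
    partition = fa.Partition(*map(int, sizes))
    n = partition.n
    J = -np.eye(n) * rng.uniform(0.5, 2.0) + 0.15 * rng.standard_normal((n, n))
    if not fa.linsys.is_hurwitz(J):
        J = J - 2.0 * np.eye(n)
    gamma_diag = rng.uniform(0.005, 0.05, size=n)
    return fa.make_system(J, rng.normal(size=n) * 0.1, gamma_diag, partition)
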