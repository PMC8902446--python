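"""Exact NESS solution and weak-coupling series.

The stationary density of dz/dt = J(z - rho) + omega is Gaussian
N(rho, Sigma*), with Sigma* solving the continuous Lyapunov equation

    J Sigma* + Sigma* J^T + 2 Gamma = 0.

The precision is H = (Sigma*)^-1 and the solenoidal matrix is defined as

    Q := J Sigma* + Gamma,

which is antisymmetric by the Lyapunov equation and satisfies the drift
reconstruction identity (Q - Gamma) H = J, i.e. the stochastic-differential
decomposition of the flow into a dissipative gradient part (-Gamma) and a
circulating, probability-current part (Q).  Q = 0 recovers detailed balance
(equilibrium), which for symmetric J gives Sigma* = -J^-1 Gamma.

For weakly coupled drifts J = -I + C the module also provides truncated
power series in C for Sigma*, H, Q and the inverse blanket covariance,
computed by exact order-tracked recursions (never by numerically
subtracting exact solutions):

    Sigma*:  S_0 = Gamma,  S_k = (C S_{k-1} + S_{k-1} C^T) / 2
    Q:       Q_0 = 0,      Q_k = C S_{k-1} - S_k        (antisymmetric per order)
    H:       Neumann inversion of the Sigma* series (homogeneous noise)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .exceptions import DegenerateDensityError, StabilityError, UnsupportedModeError
from .linsys import Partition, PartitionedLinearSystem, is_hurwitz

#: Relative tolerances the exact solution must meet (see class docstrings).
LYAPUNOV_RTOL = 1e-10
ANTISYMMETRY_RTOL = 1e-10
RECONSTRUCTION_RTOL = 1e-8


@dataclass(frozen=True)
class StationaryDensity:
    """NESS summary: covariance Sigma*, precision H, solenoidal Q, mean rho.

    ``residuals`` records the Frobenius norms of the defining identities:
    ``lyapunov`` = ||J Sigma + Sigma J^T + 2 Gamma||, ``antisymmetry`` =
    ||Q + Q^T||, ``reconstruction`` = ||(Q - Gamma) H - J||.
    """

    Sigma: np.ndarray
    H: np.ndarray
    Q: np.ndarray
    rho: np.ndarray
    residuals: dict

    @property
    def n(self) -> int:
        return self.Sigma.shape[0]


@dataclass(frozen=True)
class SeriesApproximation:
    """Truncated weak-coupling expansion of a NESS quantity.

    ``terms[k]`` is the exact order-k coefficient matrix; ``value`` is their
    sum through the truncation ``order``.  ``epsilon_scale`` is the nominal
    coupling magnitude, recorded for error reporting only.
    """

    quantity: str  # Sigma | H | Q | SigmaBBinv
    order: int
    value: np.ndarray
    terms: tuple[np.ndarray, ...]
    epsilon_scale: float | None = None


def solve_stationary_covariance(
    system: PartitionedLinearSystem,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve J Sigma + Sigma J^T + 2 Gamma = 0 for Sigma* and H = Sigma*^-1.

    Uses the Bartels-Stewart solver; Sigma is symmetrized before inversion
    and H is obtained from a Cholesky solve, not an explicit inverse.
    Raises :class:`DegenerateDensityError` when Sigma* is numerically
    singular (e.g. zero noise).
    """
    J, gamma = system.J, system.gamma
    if not is_hurwitz(J):
        raise StabilityError("J is not Hurwitz; the Lyapunov equation has no NESS solution")
    Sigma = scipy.linalg.solve_continuous_lyapunov(J, -2.0 * gamma)
    Sigma = 0.5 * (Sigma + Sigma.T)
    evals = np.linalg.eigvalsh(Sigma)
    if evals[0] <= 1e-12 * max(evals[-1], 0.0) or evals[-1] <= 0.0:
        raise DegenerateDensityError(
            f"stationary covariance is numerically singular (eigenvalues in "
            f"[{evals[0]:.3g}, {evals[-1]:.3g}]); precision unavailable"
        )
    cho = scipy.linalg.cho_factor(Sigma)
    H = scipy.linalg.cho_solve(cho, np.eye(system.n))
    H = 0.5 * (H + H.T)
    return Sigma, H


def solve_solenoidal(
    system: PartitionedLinearSystem,
    Sigma: np.ndarray,
    q_sign: int = +1,
) -> np.ndarray:
    """Solenoidal matrix Q = J Sigma* + Gamma (antisymmetric).

    ``q_sign=-1`` returns the opposite sign convention, which solves
    J Q + Q J^T = J Gamma - Gamma J^T instead of its negative.
    """
    if q_sign not in (+1, -1):
        raise ValueError("q_sign must be +1 or -1")
    return q_sign * (system.J @ Sigma + system.gamma)


def solve_stationary(
    system: PartitionedLinearSystem, q_sign: int = +1
) -> StationaryDensity:
    """Full NESS summary with defining-identity residuals recorded."""
    Sigma, H = solve_stationary_covariance(system)
    Q = solve_solenoidal(system, Sigma, q_sign=q_sign)
    J, gamma = system.J, system.gamma
    residuals = {
        "lyapunov": float(np.linalg.norm(J @ Sigma + Sigma @ J.T + 2 * gamma)),
        "antisymmetry": float(np.linalg.norm(Q + Q.T)),
        "reconstruction": float(np.linalg.norm((q_sign * Q - gamma) @ H - J)),
    }
    return StationaryDensity(Sigma=Sigma, H=H, Q=Q, rho=system.rho.copy(), residuals=residuals)


# ---------------------------------------------------------------------------
# weak-coupling series (J = -I + C)
# ---------------------------------------------------------------------------


def _sigma_terms(C: np.ndarray, gamma: np.ndarray, order: int) -> list[np.ndarray]:
    """Order-k coefficients of Sigma* for J = -I + C."""
    terms = [gamma.copy()]
    for _ in range(order):
        prev = terms[-1]
        terms.append(0.5 * (C @ prev + prev @ C.T))
    return terms


def covariance_series(
    C: np.ndarray,
    gamma: np.ndarray,
    order: int,
    epsilon_scale: float | None = None,
) -> SeriesApproximation:
    """Weak-coupling expansion of Sigma* through the given order.

    Order 2 equals Gamma + (C Gamma + Gamma C^T)/2
    + (C^2 Gamma + 2 C Gamma C^T + Gamma (C^T)^2)/4 exactly; the remainder
    of the order-k truncation is O(C^{k+1}).
    """
    C = np.asarray(C, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if order < 0:
        raise ValueError("order must be >= 0")
    terms = _sigma_terms(C, gamma, order)
    return SeriesApproximation(
        quantity="Sigma",
        order=order,
        value=sum(terms),
        terms=tuple(terms),
        epsilon_scale=epsilon_scale,
    )


def _neumann_inverse_terms(unit_terms: list[np.ndarray]) -> list[np.ndarray]:
    """Order-k terms of (I + sum_k T_k)^-1 given T_0 = I perturbation terms.

    ``unit_terms[k]`` for k >= 1 are the order-k terms of the matrix being
    inverted, normalized so the order-0 term is the identity.
    """
    n = unit_terms[0].shape[0]
    inv_terms = [np.eye(n)]
    for k in range(1, len(unit_terms)):
        acc = np.zeros((n, n))
        for j in range(1, k + 1):
            acc -= unit_terms[j] @ inv_terms[k - j]
        inv_terms.append(acc)
    return inv_terms


def hessian_series(
    C: np.ndarray,
    sigma: float,
    order: int,
    epsilon_scale: float | None = None,
) -> SeriesApproximation:
    """Neumann-series expansion of H = (Sigma*)^-1 for Gamma = sigma^2 I.

    Order 2 equals sigma^-2 (I - (C + C^T)/2 + (C^T C - C C^T)/4).
    Homogeneous noise only.
    """
    C = np.asarray(C, dtype=float)
    if sigma <= 0:
        raise UnsupportedModeError("hessian series requires sigma > 0")
    n = C.shape[0]
    # Sigma* = sigma^2 (I + sum_{k>=1} T_k) with T_k independent of sigma
    unit_terms = [t / sigma**2 for t in _sigma_terms(C, sigma**2 * np.eye(n), order)]
    inv_terms = _neumann_inverse_terms(unit_terms)
    terms = [t / sigma**2 for t in inv_terms]
    return SeriesApproximation(
        quantity="H",
        order=order,
        value=sum(terms),
        terms=tuple(terms),
        epsilon_scale=epsilon_scale,
    )


def solenoidal_series(
    C: np.ndarray,
    gamma: np.ndarray,
    order: int,
    epsilon_scale: float | None = None,
) -> SeriesApproximation:
    """Weak-coupling expansion of Q = J Sigma* + Gamma.

    Order 2 equals (C Gamma - Gamma C^T)/2 + (C^2 Gamma - Gamma (C^2)^T)/4;
    each order-k term is exactly antisymmetric.
    """
    C = np.asarray(C, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if order < 0:
        raise ValueError("order must be >= 0")
    s_terms = _sigma_terms(C, gamma, order)
    terms = [np.zeros_like(gamma)]
    for k in range(1, order + 1):
        terms.append(C @ s_terms[k - 1] - s_terms[k])
    return SeriesApproximation(
        quantity="Q",
        order=order,
        value=sum(terms),
        terms=tuple(terms),
        epsilon_scale=epsilon_scale,
    )


def blanket_inverse_series(
    C: np.ndarray,
    sigma: float,
    partition: Partition,
    order: int = 1,
    epsilon_scale: float | None = None,
) -> SeriesApproximation:
    """Neumann expansion of the inverse blanket covariance (Sigma*_bb)^-1.

    Order 1 equals sigma^-2 (I - (C_bb + C_bb^T)/2) on the blanket block.
    Homogeneous noise Gamma = sigma^2 I only.
    """
    C = np.asarray(C, dtype=float)
    if sigma <= 0:
        raise UnsupportedModeError("blanket inverse series requires sigma > 0")
    n = C.shape[0]
    b = partition.slices["b"]
    full_terms = _sigma_terms(C, sigma**2 * np.eye(n), order)
    # restriction to the blanket block is linear, so it commutes with the
    # order decomposition; invert the restricted series by Neumann recursion
    unit_terms = [t[b, b] / sigma**2 for t in full_terms]
    inv_terms = _neumann_inverse_terms(unit_terms)
    terms = [t / sigma**2 for t in inv_terms]
    return SeriesApproximation(
        quantity="SigmaBBinv",
        order=order,
        value=sum(terms),
        terms=tuple(terms),
        epsilon_scale=epsilon_scale,
    )
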