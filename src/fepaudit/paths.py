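"""Trajectory simulation and the divergence between the true conditional-mode
path and its free-energy ("marginal flow") surrogate.

The system is integrated by Euler-Maruyama,

    z_{t+dt} = z_t + dt J (z_t - rho) + sqrt(2 dt) Gamma^{1/2} xi,

which is O(dt)-exact in distribution for linear drift.  Two external-state
summaries are then derived from the same realized blanket path b_t:

* the true conditional mode m_y(b_t), a fixed linear image of b_t;
* the surrogate m~_y(t) obtained by integrating the marginal-flow ODE
  dm~_y/dt = (J_yy Sigma*_yb (Sigma*_bb)^g + J_yb)(b_t - rho_b),

the path a system would follow if it strictly descended the free energy
gradient.  m_y(b_t) is stationary (bounded in probability) while m~_y
integrates unmodelled fluctuations and random-walks away; the comparison
quantifies this divergence.  Time derivatives are never estimated by
finite-differencing noisy paths: all comparisons are between integrated
paths, which is well-posed despite the formal white-noise term in
dm_y(b_t)/dt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import StructureError
from .geometry import ConditionalMoments, conditional_moments
from .linsys import Partition, PartitionedLinearSystem, make_system
from .stationary import StationaryDensity, solve_stationary


@dataclass(frozen=True)
class Trajectory:
    """An Euler-Maruyama sample path on the grid (0, dt, ..., T)."""

    times: np.ndarray
    states: np.ndarray  # (len(times), n)
    dt: float
    seed: int | None
    scheme: str = "euler_maruyama"
    stable_step: bool = True

    @property
    def n(self) -> int:
        return self.states.shape[1]


@dataclass(frozen=True)
class PathComparison:
    """Divergence metrics between m_y(b_t) and the surrogate m~_y(t).

    ``corr`` is the per-coordinate linear correlation; ensemble statistics
    (``var_growth_slope``, the slope of Var[m~_y(t)] over the second half of
    the run; ``var_ratio`` = Var(T)/Var(T/4); ``var_bound_true`` =
    max_t Var[m_y(b_t)]) are filled when an ensemble of path pairs is given.
    """

    times: np.ndarray
    m_y_path: np.ndarray
    m_tilde_path: np.ndarray
    rmse: float
    corr: np.ndarray
    var_growth_slope: float | None = None
    var_ratio: float | None = None
    var_bound_true: float | None = None
    ensemble_variances: pd.DataFrame | None = None


def simulate(
    system: PartitionedLinearSystem,
    z0: np.ndarray | None = None,
    dt: float = 1e-2,
    T: float = 100.0,
    seed: int | None = None,
) -> Trajectory:
    """Euler-Maruyama integration of dz/dt = J(z - rho) + omega.

    Per-step noise covariance is 2*Gamma*dt.  A step with
    dt * max|eig(J)| >= 0.1 is integrated anyway but flagged and warned
    about.  Deterministic given the seed.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_steps = int(round(T / dt))
    spec_radius = float(np.max(np.abs(np.linalg.eigvals(system.J))))
    stable = dt * spec_radius < 0.1
    if not stable:
        warnings.warn(
            f"dt*max|eig(J)| = {dt * spec_radius:.3g} >= 0.1; the Euler step may "
            "be inaccurate",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    n = system.n
    z = system.rho.copy() if z0 is None else np.asarray(z0, dtype=float).copy()
    states = np.empty((n_steps + 1, n))
    states[0] = z
    noise_scale = np.sqrt(2.0 * dt * system.gamma_diagonal)
    J, rho = system.J, system.rho
    for k in range(n_steps):
        z = z + dt * (J @ (z - rho)) + noise_scale * rng.standard_normal(n)
        states[k + 1] = z
    times = dt * np.arange(n_steps + 1)
    return Trajectory(times=times, states=states, dt=dt, seed=seed, stable_step=stable)


def simulate_ensemble_states(
    system: PartitionedLinearSystem,
    n_members: int,
    dt: float = 1e-2,
    T: float = 50.0,
    seed: int | None = None,
    z0: np.ndarray | None = None,
) -> np.ndarray:
    """Final states of ``n_members`` Euler-Maruyama paths, propagated jointly.

    All members share one seeded generator; returns an (n_members, n) array
    of states at time T.  Used for transient-moment and stationarity checks,
    where only the terminal ensemble is needed.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_steps = int(round(T / dt))
    rng = np.random.default_rng(seed)
    n = system.n
    Z = np.tile(system.rho if z0 is None else np.asarray(z0, dtype=float), (n_members, 1))
    noise_scale = np.sqrt(2.0 * dt * system.gamma_diagonal)
    J, rho = system.J, system.rho
    for _ in range(n_steps):
        Z = Z + dt * (Z - rho) @ J.T + noise_scale * rng.standard_normal((n_members, n))
    return Z


def blanket_path(trajectory: Trajectory, partition: Partition) -> np.ndarray:
    """The realized blanket path b_t (rows of the trajectory's b block)."""
    return trajectory.states[:, partition.slices["b"]]


def true_mode_path(
    trajectory: Trajectory, moments: ConditionalMoments, partition: Partition
) -> np.ndarray:
    """Pointwise conditional mode m_y(b_t) along a trajectory."""
    b = blanket_path(trajectory, partition)
    return moments.rho_y + (b - moments.rho_b) @ moments.gain_y.T


def marginal_flow_path(
    trajectory: Trajectory,
    system: PartitionedLinearSystem,
    moments: ConditionalMoments,
    m0: np.ndarray | None = None,
) -> np.ndarray:
    """Euler integration of the marginal-flow surrogate m~_y(t).

    Driven by the realized blanket path; starts at m_y(b_0) unless ``m0``
    is given.  Deterministic given the trajectory.
    """
    p = system.partition
    b = blanket_path(trajectory, p)
    A = p.block(system.J, "y", "y") @ moments.gain_y + p.block(system.J, "y", "b")
    drive = (b - moments.rho_b) @ A.T
    m = np.empty((len(b), p.ny))
    m[0] = moments.m_y(b[0]) if m0 is None else np.asarray(m0, dtype=float)
    dt = trajectory.dt
    for k in range(len(b) - 1):
        m[k + 1] = m[k] + dt * drive[k]
    return m


def _ensemble_variance(paths: list[np.ndarray]) -> np.ndarray:
    """Coordinate-averaged ensemble variance at each time point."""
    stack = np.stack(paths)  # (members, time, coords)
    return stack.var(axis=0, ddof=1).mean(axis=1)


def compare_paths(
    m_y_path: np.ndarray,
    m_tilde_path: np.ndarray,
    times: np.ndarray,
    ensemble: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> PathComparison:
    """RMSE and per-coordinate correlation between the two paths; with an
    ensemble of (m_y, m~_y) pairs, also the diffusive-growth statistics of
    Var[m~_y(t)] and the stationary plateau of Var[m_y(b_t)]."""
    m_y_path = np.asarray(m_y_path, dtype=float)
    m_tilde_path = np.asarray(m_tilde_path, dtype=float)
    if m_y_path.shape != m_tilde_path.shape:
        raise ValueError(
            f"path shapes differ: {m_y_path.shape} vs {m_tilde_path.shape}"
        )
    rmse = float(np.sqrt(np.mean((m_y_path - m_tilde_path) ** 2)))
    corr = np.array(
        [
            np.corrcoef(m_y_path[:, j], m_tilde_path[:, j])[0, 1]
            if np.std(m_y_path[:, j]) > 0 and np.std(m_tilde_path[:, j]) > 0
            else 1.0 if np.allclose(m_y_path[:, j], m_tilde_path[:, j]) else 0.0
            for j in range(m_y_path.shape[1])
        ]
    )
    slope = ratio = bound = None
    var_df = None
    if ensemble is not None:
        var_true = _ensemble_variance([pair[0] for pair in ensemble])
        var_tilde = _ensemble_variance([pair[1] for pair in ensemble])
        var_df = pd.DataFrame(
            {"t": times, "var_m_y": var_true, "var_m_tilde": var_tilde}
        )
        half = len(times) // 2
        slope = float(np.polyfit(times[half:], var_tilde[half:], 1)[0])
        i_quarter = (len(times) - 1) // 4
        denom = var_tilde[i_quarter]
        ratio = float(var_tilde[-1] / denom) if denom > 0 else np.inf
        bound = float(np.max(var_true))
    return PathComparison(
        times=np.asarray(times, dtype=float),
        m_y_path=m_y_path,
        m_tilde_path=m_tilde_path,
        rmse=rmse,
        corr=corr,
        var_growth_slope=slope,
        var_ratio=ratio,
        var_bound_true=bound,
        ensemble_variances=var_df,
    )


def ensemble_path_comparison(
    system: PartitionedLinearSystem,
    n_members: int = 32,
    dt: float = 1e-2,
    T: float = 100.0,
    seed: int = 0,
    z0: np.ndarray | None = None,
) -> PathComparison:
    """Simulate an ensemble of trajectories (seeds seed, seed+1, ...) and
    compare m_y(b_t) with m~_y(t); the returned comparison carries the
    first member's paths plus the ensemble variance statistics."""
    density = solve_stationary(system)
    moments = conditional_moments(density, system.partition)
    pairs = []
    times = None
    for k in range(n_members):
        traj = simulate(system, z0=z0, dt=dt, T=T, seed=seed + k)
        times = traj.times
        m_y = true_mode_path(traj, moments, system.partition)
        m_tilde = marginal_flow_path(traj, system, moments)
        pairs.append((m_y, m_tilde))
    return compare_paths(pairs[0][0], pairs[0][1], times, ensemble=pairs)


def first_order_flow_matrices(
    system: PartitionedLinearSystem, partition: Partition | None = None
) -> dict[str, np.ndarray]:
    """First-order and exact coefficient matrices of (b - rho_b) in the two
    flow equations for weakly coupled canonical systems (Gamma = sigma^2 I):

        A_true  = -(C_yb + C_by^T)/2    (true conditional-mode drift)
        A_tilde = -(-C_yb + C_by^T)/2   (marginal-flow surrogate drift)

    The surrogate reverses the sign of C_yb; when C_yb = C_by^T (symmetric
    chain) A_tilde vanishes while A_true = -C_yb does not.  The exact
    counterparts are A_true_exact = G_y (J_by G_y + J_bb + J_bx G_x) and
    A_tilde_exact = J_yy G_y + J_yb, with G the conditional gains; both
    first-order matrices are O(epsilon^2) from their exact counterparts.
    """
    p = system.partition if partition is None else partition
    if not system.is_homogeneous:
        raise StructureError("first-order flow matrices require homogeneous noise")
    C = system.C
    sl = p.slices
    for (r, c) in (("y", "x"), ("s", "x"), ("a", "y"), ("x", "y")):
        if np.any(C[sl[r], sl[c]] != 0.0):
            raise StructureError(
                f"first-order flow matrices require the canonical mask; C_{r}{c} != 0"
            )
    Cyb = p.block(C, "y", "b")
    Cby = p.block(C, "b", "y")
    A_true = -0.5 * (Cyb + Cby.T)
    A_tilde = -0.5 * (-Cyb + Cby.T)
    density = solve_stationary(system)
    moments = conditional_moments(density, p)
    J = system.J
    A_true_exact = moments.gain_y @ (
        p.block(J, "b", "y") @ moments.gain_y
        + p.block(J, "b", "b")
        + p.block(J, "b", "x") @ moments.gain_x
    )
    A_tilde_exact = p.block(J, "y", "y") @ moments.gain_y + p.block(J, "y", "b")
    return {
        "A_true": A_true,
        "A_tilde": A_tilde,
        "A_true_exact": A_true_exact,
        "A_tilde_exact": A_tilde_exact,
    }


def bivariate_demo(
    c: float,
    sigma: float = 0.1,
    grid: np.ndarray | None = None,
) -> dict:
    """Spiral-flow counterexample on two variables (y, b).

    The drift J = [[-1, c], [-c, -1]] has eigenvalues -1 +/- ci: a global
    attractor at y = b = 0 approached along a spiral (solenoidal) flow with
    Q = sigma^2 c [[0, 1], [-1, 0]].  The conditional average flow of y
    given b, <f_y>_b = c*b (here Sigma* = sigma^2 I so m_y(b) = 0), points
    away from the conditional mode whenever c*b and y disagree in sign with
    the attracting radial flow — it reads as a monotonic ascent in b even
    though every trajectory decays to the origin in expectation.

    Returns the system, its NESS, the true flow field f(z) = J z on the
    grid, and the conditional flow as a field over b.
    """
    if c == 0:
        # equilibrium: still well-defined, Q = 0 and purely mean-reverting
        pass
    J = np.array([[-1.0, c], [-c, -1.0]])
    partition = Partition(ny=1, ns=1, na=0, nx=0)  # states (y, b): b is sensory
    system = make_system(
        J=J,
        rho=np.zeros(2),
        gamma=np.full(2, sigma**2),
        partition=partition,
        structure="unconstrained",
    )
    density = solve_stationary(system)
    moments = conditional_moments(density, partition)
    if grid is None:
        grid = np.linspace(-3.0, 3.0, 21) * max(sigma, 1e-12)
    Y, B = np.meshgrid(grid, grid, indexing="ij")
    U = J[0, 0] * Y + J[0, 1] * B  # dy/dt
    V = J[1, 0] * Y + J[1, 1] * B  # db/dt
    cond_flow = np.array(
        [
            float(
                J[0, 0] * moments.m_y(np.array([b]))[0] + J[0, 1] * b
            )
            for b in grid
        ]
    )
    return {
        "system": system,
        "density": density,
        "eigenvalues": np.linalg.eigvals(J),
        "Q": density.Q,
        "grid": grid,
        "true_flow_field": {"y": Y, "b": B, "dy": U, "db": V},
        "conditional_flow_b": grid,
        "conditional_flow_y": cond_flow,
        "gain_y": moments.gain_y,
    }
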