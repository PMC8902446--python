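"""Conditional-Gaussian inference geometry.

Given the NESS density N(rho, Sigma*) of a partitioned system, conditioning
on a blanket state b = (s, a) gives Gaussian conditionals whose modes are
linear in b:

    m_y(b) = rho_y + Sigma*_yb (Sigma*_bb)^g (b - rho_b),
    m_x(b) = rho_x + Sigma*_xb (Sigma*_bb)^g (b - rho_b),

with (.)^g the Moore-Penrose inverse when the blanket block is singular.
On top of these the module builds:

* the synchronisation map sigma relating most likely internal and external
  states, m_y = sigma(m_x), and its inverse;
* surprise -log p(b), the Gaussian-Gaussian KL divergence, and the
  variational free energy F(theta, b) = surprise + KL with its exact
  gradient (for linear systems the Laplace quadratic form is exact, so no
  approximation is involved);
* conditional average ("marginal") flows <f_y>_b, <f_x>_b;
* the gradient-flow identity check: under an exact Markov blanket and
  block-diagonal Q, <f_y>(theta, b) = (Q_yy - Gamma_yy) grad_theta F exactly;
* the flow map phi between marginal flows and its mismatch with grad sigma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.stats import qmc

from .exceptions import DegenerateDensityError, MappingUndefinedError
from .linsys import Partition, PartitionedLinearSystem
from .stationary import StationaryDensity


@dataclass(frozen=True)
class ConditionalMoments:
    """Linear gains and conditional covariances of y and x given the blanket.

    ``gain_y`` = Sigma*_yb (Sigma*_bb)^g (n_y x n_b), similarly ``gain_x``.
    ``cond_cov_y`` is the Schur complement Sigma_yy - Sigma_yb Sigma_bb^g
    Sigma_by, which is correct with or without a Markov blanket; the
    precision-based alternative (H_yy)^-1 agrees with it only when H_yx = 0,
    so ``mb_cov_gap`` (their Frobenius distance) doubles as a blanket
    diagnostic.
    """

    gain_y: np.ndarray
    gain_x: np.ndarray
    rho_y: np.ndarray
    rho_x: np.ndarray
    rho_b: np.ndarray
    cond_cov_y: np.ndarray
    cond_cov_x: np.ndarray
    cond_cov_y_precision: np.ndarray
    mb_cov_gap: float
    used_pseudoinverse: bool

    def m_y(self, b: np.ndarray) -> np.ndarray:
        """Most likely external state given blanket state b."""
        return self.rho_y + self.gain_y @ (np.asarray(b, dtype=float) - self.rho_b)

    def m_x(self, b: np.ndarray) -> np.ndarray:
        """Most likely internal state given blanket state b."""
        return self.rho_x + self.gain_x @ (np.asarray(b, dtype=float) - self.rho_b)


@dataclass(frozen=True)
class VariationalModel:
    """Gaussian variational density q(y | theta) = N(theta, Sigma_theta)."""

    theta: np.ndarray
    Sigma_theta: np.ndarray

    def __post_init__(self) -> None:
        S = np.asarray(self.Sigma_theta, dtype=float)
        if not np.allclose(S, S.T):
            raise ValueError("Sigma_theta must be symmetric")
        if np.linalg.eigvalsh(S)[0] <= 0:
            raise ValueError("Sigma_theta must be positive definite")


@dataclass(frozen=True)
class FreeEnergyReport:
    """Surprise, KL divergence, free energy F = surprise + KL (nats), and
    the exact gradient of F with respect to the variational mean theta."""

    surprise: float
    kl: float
    free_energy: float
    gradient: np.ndarray


@dataclass(frozen=True)
class LinearMap:
    """Affine map v -> offset + matrix (v - center)."""

    matrix: np.ndarray
    center: np.ndarray
    offset: np.ndarray

    def __call__(self, v: np.ndarray) -> np.ndarray:
        return self.offset + self.matrix @ (np.asarray(v, dtype=float) - self.center)

    @property
    def grad(self) -> np.ndarray:
        return self.matrix


def conditional_moments(
    density: StationaryDensity, partition: Partition
) -> ConditionalMoments:
    """Conditional gains and covariances of y and x given the blanket b."""
    p = partition
    Sigma, H, rho = density.Sigma, density.H, density.rho
    Sbb = p.block(Sigma, "b", "b")
    cond = np.linalg.cond(Sbb)
    used_pinv = not np.isfinite(cond) or cond > 1e12
    Sbb_g = np.linalg.pinv(Sbb) if used_pinv else np.linalg.inv(Sbb)
    Syb = p.block(Sigma, "y", "b")
    Sxb = p.block(Sigma, "x", "b")
    gain_y = Syb @ Sbb_g
    gain_x = Sxb @ Sbb_g
    cov_y = p.block(Sigma, "y", "y") - gain_y @ Syb.T
    cov_x = p.block(Sigma, "x", "x") - gain_x @ Sxb.T
    cov_y = 0.5 * (cov_y + cov_y.T)
    cov_x = 0.5 * (cov_x + cov_x.T)
    Hyy = p.block(H, "y", "y")
    cov_y_prec = np.linalg.inv(Hyy)
    return ConditionalMoments(
        gain_y=gain_y,
        gain_x=gain_x,
        rho_y=p.sub(rho, "y"),
        rho_x=p.sub(rho, "x"),
        rho_b=p.sub(rho, "b"),
        cond_cov_y=cov_y,
        cond_cov_x=cov_x,
        cond_cov_y_precision=cov_y_prec,
        mb_cov_gap=float(np.linalg.norm(cov_y - cov_y_prec)),
        used_pseudoinverse=used_pinv,
    )


def _solve_or_pinv(M: np.ndarray, name: str, square_needed: bool = False) -> np.ndarray:
    """Inverse of a gain-defining covariance block, or a left pseudo-inverse
    for tall full-column-rank blocks."""
    rows, cols = M.shape
    if rows < cols:
        raise MappingUndefinedError(
            f"{name} is {rows}x{cols}: rank condition requires at least as many "
            "rows as blanket states"
        )
    if square_needed and rows != cols:
        raise MappingUndefinedError(f"{name} must be square ({rows}x{cols} given)")
    if np.linalg.matrix_rank(M) < cols:
        raise MappingUndefinedError(f"{name} is rank deficient; mapping undefined")
    return np.linalg.pinv(M) if rows != cols else np.linalg.inv(M)


def sigma_map(
    moments: ConditionalMoments, density: StationaryDensity, partition: Partition
) -> LinearMap:
    """The synchronisation map sigma with m_y(b) = sigma(m_x(b)).

    sigma(v) = rho_y + Sigma*_yb (Sigma*_xb)^-1 (v - rho_x); requires
    Sigma*_xb of full column rank (hence n_x >= n_b).
    """
    Syb = partition.block(density.Sigma, "y", "b")
    Sxb = partition.block(density.Sigma, "x", "b")
    Sxb_inv = _solve_or_pinv(Sxb, "Sigma*_xb")
    return LinearMap(matrix=Syb @ Sxb_inv, center=moments.rho_x, offset=moments.rho_y)


def sigma_inverse(
    moments: ConditionalMoments, density: StationaryDensity, partition: Partition
) -> LinearMap:
    """Inverse synchronisation map with m_x(b) = sigma^-1(m_y(b)).

    Requires Sigma*_yb of full column rank (hence n_y >= n_b).
    """
    Syb = partition.block(density.Sigma, "y", "b")
    Sxb = partition.block(density.Sigma, "x", "b")
    Syb_inv = _solve_or_pinv(Syb, "Sigma*_yb")
    return LinearMap(matrix=Sxb @ Syb_inv, center=moments.rho_y, offset=moments.rho_x)


def surprise(b: np.ndarray, density: StationaryDensity, partition: Partition) -> float:
    """Surprise -log p(b) of a blanket state under the NESS marginal.

    Equals ((b-rho_b)^T (Sigma*_bb)^-1 (b-rho_b) + log det(2 pi Sigma*_bb))/2.
    """
    b = np.asarray(b, dtype=float)
    Sbb = partition.block(density.Sigma, "b", "b")
    rho_b = partition.sub(density.rho, "b")
    try:
        cho = scipy.linalg.cho_factor(Sbb)
    except scipy.linalg.LinAlgError as exc:
        raise DegenerateDensityError("Sigma*_bb is not positive definite") from exc
    dev = b - rho_b
    maha = float(dev @ scipy.linalg.cho_solve(cho, dev))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    nb = Sbb.shape[0]
    return 0.5 * (maha + logdet + nb * np.log(2.0 * np.pi))


def _gaussian_kl(
    mean_q: np.ndarray, cov_q: np.ndarray, mean_p: np.ndarray, cov_p: np.ndarray
) -> float:
    """KL(N(mean_q, cov_q) || N(mean_p, cov_p)) in nats."""
    k = len(mean_q)
    cho_p = scipy.linalg.cho_factor(cov_p)
    dev = mean_p - mean_q
    maha = float(dev @ scipy.linalg.cho_solve(cho_p, dev))
    trace = float(np.trace(scipy.linalg.cho_solve(cho_p, cov_q)))
    logdet_p = 2.0 * float(np.sum(np.log(np.diag(cho_p[0]))))
    sign, logdet_q = np.linalg.slogdet(cov_q)
    if sign <= 0:
        raise ValueError("cov_q must be positive definite")
    return 0.5 * (trace + maha - k + logdet_p - logdet_q)


def free_energy(
    model: VariationalModel,
    b: np.ndarray,
    density: StationaryDensity,
    partition: Partition,
    moments: ConditionalMoments | None = None,
) -> FreeEnergyReport:
    """Variational free energy F(theta, b) = -log p(b) + KL(q || p(y|b)).

    Both densities are Gaussian so the KL is closed-form and the bound
    F >= surprise is exact, attained iff q equals the conditional.
    The gradient is grad_theta F = (Sigma_y|b)^-1 (theta - m_y(b)).
    """
    if moments is None:
        moments = conditional_moments(density, partition)
    s = surprise(b, density, partition)
    my = moments.m_y(b)
    kl = _gaussian_kl(model.theta, model.Sigma_theta, my, moments.cond_cov_y)
    grad = np.linalg.solve(moments.cond_cov_y, model.theta - my)
    return FreeEnergyReport(surprise=s, kl=kl, free_energy=s + kl, gradient=grad)


def marginal_flow_y(
    b: np.ndarray,
    system: PartitionedLinearSystem,
    moments: ConditionalMoments,
) -> np.ndarray:
    """Conditional average flow <f_y>_b (exact for linear drift):

        <f_y>_b = J_yy (m_y(b) - rho_y) + J_yb (b - rho_b)
                  [+ J_yx (m_x(b) - rho_x) when the canonical mask is violated]
    """
    b = np.asarray(b, dtype=float)
    p = system.partition
    J = system.J
    flow = p.block(J, "y", "y") @ (moments.m_y(b) - moments.rho_y)
    flow = flow + p.block(J, "y", "b") @ (b - moments.rho_b)
    Jyx = p.block(J, "y", "x")
    if np.any(Jyx != 0.0):  # cross term needed outside the canonical mask
        flow = flow + Jyx @ (moments.m_x(b) - moments.rho_x)
    return flow


def marginal_flow_x(
    b: np.ndarray,
    system: PartitionedLinearSystem,
    moments: ConditionalMoments,
) -> np.ndarray:
    """Conditional average flow <f_x>_b, analogous to :func:`marginal_flow_y`."""
    b = np.asarray(b, dtype=float)
    p = system.partition
    J = system.J
    flow = p.block(J, "x", "x") @ (moments.m_x(b) - moments.rho_x)
    flow = flow + p.block(J, "x", "b") @ (b - moments.rho_b)
    Jxy = p.block(J, "x", "y")
    if np.any(Jxy != 0.0):
        flow = flow + Jxy @ (moments.m_y(b) - moments.rho_y)
    return flow


def _probe_points(
    moments: ConditionalMoments,
    density: StationaryDensity,
    partition: Partition,
    n_probes: int,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic quasi-random (theta, b) probes within +/-3 standard
    deviations (blanket marginal for b, conditional for theta)."""
    ny = partition.ny
    nb = partition.nb
    halton = qmc.Halton(d=ny + nb, scramble=False)
    u = halton.random(n_probes + 1)[1:]  # drop the origin sample
    std_b = np.sqrt(np.diag(partition.block(density.Sigma, "b", "b")))
    std_y = np.sqrt(np.diag(moments.cond_cov_y))
    probes = []
    for row in u:
        b = moments.rho_b + 3.0 * (2.0 * row[:nb] - 1.0) * std_b
        theta = moments.m_y(b) + 3.0 * (2.0 * row[nb:] - 1.0) * std_y
        probes.append((theta, b))
    return probes


def gradient_flow_identity_residual(
    system: PartitionedLinearSystem,
    density: StationaryDensity,
    partition: Partition | None = None,
    n_probes: int = 16,
) -> float:
    """Worst-case relative residual of the gradient-flow identity

        f_y(theta, b) = (Q_yy - Gamma_yy) (Sigma_y|b)^-1 (theta - m_y(b)),

    i.e. the claim that the flow of external states descends the free energy
    gradient at rate Gamma_yy - Q_yy.  The identity is exact (residual below
    1e-8) when H_yx = 0 and the Q blocks coupling y to (b, x) vanish, since
    then J_yy = (Q_yy - Gamma_yy) H_yy and J_yb = (Q_yy - Gamma_yy) H_yb;
    generically it fails at order epsilon.
    """
    p = system.partition if partition is None else partition
    moments = conditional_moments(density, p)
    Qyy = p.block(density.Q, "y", "y")
    Gyy = p.block(system.gamma, "y", "y")
    rate = Qyy - Gyy
    cho = scipy.linalg.cho_factor(moments.cond_cov_y)
    worst = 0.0
    scale = 0.0
    for theta, b in _probe_points(moments, density, p, n_probes):
        flow = (
            p.block(system.J, "y", "y") @ (theta - moments.rho_y)
            + p.block(system.J, "y", "b") @ (b - moments.rho_b)
        )
        grad = scipy.linalg.cho_solve(cho, theta - moments.m_y(b))
        rhs = rate @ grad
        worst = max(worst, float(np.linalg.norm(flow - rhs)))
        scale = max(scale, float(np.linalg.norm(flow)), float(np.linalg.norm(rhs)))
    return worst / max(scale, 1e-300)


def phi_map(
    system: PartitionedLinearSystem,
    density: StationaryDensity,
    moments: ConditionalMoments | None = None,
) -> np.ndarray:
    """The linear map phi between conditional average flows,
    <f_y>_b = phi(<f_x>_b).

    With square invertible blanket-covariance blocks (n_y = n_x = n_b),

        phi = (J_yy Sigma*_yb + J_yb Sigma*_bb)(J_xx Sigma*_xb + J_xb Sigma*_bb)^-1,

    which composes the exact flow coefficients <f_y>_b = A_y (b - rho_b),
    <f_x>_b = A_x (b - rho_b).  phi differs from grad sigma generically.
    """
    p = system.partition
    if not (p.ny == p.nb == p.nx):
        raise MappingUndefinedError(
            "phi map requires square blocks n_y = n_b = n_x "
            f"(got n_y={p.ny}, n_b={p.nb}, n_x={p.nx})"
        )
    Sigma = density.Sigma
    Syb = p.block(Sigma, "y", "b")
    Sxb = p.block(Sigma, "x", "b")
    Sbb = p.block(Sigma, "b", "b")
    for M, name in ((Syb, "Sigma*_yb"), (Sxb, "Sigma*_xb"), (Sbb, "Sigma*_bb")):
        if np.linalg.matrix_rank(M) < M.shape[1]:
            raise MappingUndefinedError(f"{name} is singular; phi undefined")
    J = system.J
    Ay = p.block(J, "y", "y") @ Syb + p.block(J, "y", "b") @ Sbb
    Ax = p.block(J, "x", "x") @ Sxb + p.block(J, "x", "b") @ Sbb
    if np.linalg.matrix_rank(Ax) < Ax.shape[1]:
        raise MappingUndefinedError("internal flow coefficient is singular; phi undefined")
    return Ay @ np.linalg.inv(Ax)


def flow_map_mismatch(
    system: PartitionedLinearSystem,
    density: StationaryDensity,
    moments: ConditionalMoments | None = None,
) -> float:
    """Relative Frobenius distance ||phi - grad sigma|| / ||grad sigma||.

    Strictly positive for generic systems: the flow map phi is not the
    gradient of the synchronisation map.
    """
    p = system.partition
    if moments is None:
        moments = conditional_moments(density, p)
    phi = phi_map(system, density, moments)
    grad_sigma = sigma_map(moments, density, p).grad
    return float(np.linalg.norm(phi - grad_sigma) / np.linalg.norm(grad_sigma))
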