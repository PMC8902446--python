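"""Partitioned linear Langevin systems and their sensorimotor structures.

A system is the Langevin dynamics

    dz/dt = J (z - rho) + omega_t,

where the state z = (y, s, a, x) is partitioned into external, sensory,
active and internal blocks, J = -I + C is a Hurwitz drift matrix, and
omega_t is Gaussian white noise with diagonal covariance 2*Gamma.  The
coupling matrix C carries the sensorimotor structure: which blocks may
drive which.  This module defines the partition bookkeeping, the structure
masks (canonical perception-action interface, unidirectional circular loop,
symmetric chain), random instance generation with Rademacher couplings
C_ij = +/-epsilon, and JSON (de)serialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .exceptions import (
    DimensionError,
    GenerationError,
    SchemaError,
    StabilityError,
    StructureError,
)

BLOCKS = ("y", "s", "a", "x")

SCHEMA_VERSION = 1

#: Default orientation of the circular loop: environment drives sensors,
#: sensors drive internal states, internal states drive action, action
#: drives the environment.  C_rc nonzero means block c drives block r.
CIRCULAR_EDGES = {
    "ysxa": (("s", "y"), ("x", "s"), ("a", "x"), ("y", "a")),
    "yaxs": (("a", "y"), ("x", "a"), ("s", "x"), ("y", "s")),
}


@dataclass(frozen=True)
class Partition:
    """Block sizes of the (y, s, a, x) state decomposition.

    The state-vector order is fixed as (y, s, a, x); the blanket b is the
    concatenation (s, a) and is therefore contiguous.
    """

    ny: int
    ns: int
    na: int
    nx: int

    def __post_init__(self) -> None:
        for name in ("ny", "ns", "na", "nx"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise DimensionError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n < 2:
            raise DimensionError("total state dimension must be at least 2")

    @property
    def n(self) -> int:
        return self.ny + self.ns + self.na + self.nx

    @property
    def nb(self) -> int:
        """Blanket size n_s + n_a."""
        return self.ns + self.na

    @property
    def slices(self) -> dict[str, slice]:
        """Index slices for the y, s, a, x blocks and the blanket b."""
        ny, ns, na, nx = self.ny, self.ns, self.na, self.nx
        return {
            "y": slice(0, ny),
            "s": slice(ny, ny + ns),
            "a": slice(ny + ns, ny + ns + na),
            "x": slice(ny + ns + na, ny + ns + na + nx),
            "b": slice(ny, ny + ns + na),
        }

    def block(self, M: np.ndarray, row: str, col: str) -> np.ndarray:
        """Submatrix of ``M`` addressed by block labels (e.g. 'y', 'b')."""
        sl = self.slices
        return M[sl[row], sl[col]]

    def sub(self, v: np.ndarray, which: str) -> np.ndarray:
        """Subvector of ``v`` addressed by a block label."""
        return v[self.slices[which]]

    def requires_all_blocks(self) -> bool:
        return min(self.ny, self.ns, self.na, self.nx) >= 1


@dataclass(frozen=True)
class StructureMask:
    """Sparsity/symmetry pattern a coupling matrix C must respect.

    ``zero_blocks`` are (row, col) block-label pairs forced to zero;
    ``symmetric_pairs`` are pairs ((i, j), (j, i)) with C_ij = C_ji^T.
    """

    zero_blocks: frozenset[tuple[str, str]] = frozenset()
    symmetric_pairs: frozenset[tuple[tuple[str, str], tuple[str, str]]] = frozenset()


_CANONICAL_ZEROS = frozenset({("y", "x"), ("s", "x"), ("a", "y"), ("x", "y")})


def structure_mask(structure: str, circular_direction: str = "ysxa") -> StructureMask:
    """Return the :class:`StructureMask` for a named sensorimotor structure.

    * ``canonical`` — the perception-action interface: f_y, f_s depend only on
      (y, s, a) and f_a, f_x only on (s, a, x), i.e. C_yx = C_sx = C_ay =
      C_xy = 0.
    * ``circular`` — a unidirectional cycle; only the four between-block
      couplings of the cycle may be nonzero, within-block entries free.
    * ``symmetric_chain`` — canonical zeros plus C_ya = C_xs = 0 and symmetric
      between-block couplings C_ys = C_sy^T, C_sa = C_as^T, C_ax = C_xa^T;
      asymmetry is allowed only inside blocks.
    * ``unconstrained`` — no constraints.
    """
    if structure == "unconstrained":
        return StructureMask()
    if structure == "canonical":
        return StructureMask(zero_blocks=_CANONICAL_ZEROS)
    if structure == "circular":
        if circular_direction not in CIRCULAR_EDGES:
            raise StructureError(f"unknown circular direction {circular_direction!r}")
        allowed = set(CIRCULAR_EDGES[circular_direction])
        zeros = {
            (r, c)
            for r in BLOCKS
            for c in BLOCKS
            if r != c and (r, c) not in allowed
        }
        return StructureMask(zero_blocks=frozenset(zeros))
    if structure == "symmetric_chain":
        zeros = set(_CANONICAL_ZEROS) | {("y", "a"), ("x", "s")}
        pairs = frozenset(
            {
                (("y", "s"), ("s", "y")),
                (("s", "a"), ("a", "s")),
                (("a", "x"), ("x", "a")),
            }
        )
        return StructureMask(zero_blocks=frozenset(zeros), symmetric_pairs=pairs)
    raise StructureError(f"unknown structure label {structure!r}")


@dataclass(frozen=True)
class PartitionedLinearSystem:
    """A validated linear Langevin system dz/dt = J(z - rho) + omega.

    Attributes
    ----------
    partition : Partition
        Block sizes of (y, s, a, x).
    J : ndarray
        Hurwitz drift matrix; ``C = J + I`` is the coupling matrix.
    rho : ndarray
        Set-point (stationary mean).
    gamma_diagonal : ndarray
        Diagonal of Gamma; the white noise has covariance 2*Gamma.
    structure : str
        Claimed sensorimotor structure label.
    seed : int or None
        Seed used by the generator, if any.
    """

    partition: Partition
    J: np.ndarray
    rho: np.ndarray
    gamma_diagonal: np.ndarray
    structure: str = "unconstrained"
    seed: int | None = None
    circular_direction: str = "ysxa"
    extra: Mapping[str, object] = field(default_factory=dict, compare=False)

    @property
    def n(self) -> int:
        return self.partition.n

    @property
    def C(self) -> np.ndarray:
        """Coupling matrix C = J + I."""
        return self.J + np.eye(self.n)

    @property
    def gamma(self) -> np.ndarray:
        """The full diagonal noise matrix Gamma."""
        return np.diag(self.gamma_diagonal)

    @property
    def is_homogeneous(self) -> bool:
        """True when Gamma = sigma^2 I."""
        g = self.gamma_diagonal
        return bool(np.all(g == g[0]))

    @property
    def sigma(self) -> float:
        """Scalar noise amplitude for homogeneous Gamma = sigma^2 I."""
        if not self.is_homogeneous:
            raise ValueError("gamma is heterogeneous; no scalar sigma")
        return float(np.sqrt(self.gamma_diagonal[0]))

    def hurwitz_margin(self) -> float:
        """-max Re(eig(J)); positive for a stable system."""
        return float(-np.max(np.linalg.eigvals(self.J).real))


def is_hurwitz(J: np.ndarray) -> bool:
    return bool(np.max(np.linalg.eigvals(J).real) < 0.0)


def _as_gamma_diagonal(gamma: np.ndarray, n: int) -> np.ndarray:
    gamma = np.asarray(gamma, dtype=float)
    if gamma.ndim == 2:
        if gamma.shape != (n, n):
            raise DimensionError(f"gamma shape {gamma.shape} != ({n}, {n})")
        if np.any(gamma - np.diag(np.diag(gamma)) != 0.0):
            raise DimensionError("gamma must be diagonal")
        gamma = np.diag(gamma)
    elif gamma.ndim == 1:
        if gamma.shape != (n,):
            raise DimensionError(f"gamma diagonal length {gamma.shape[0]} != {n}")
    else:
        raise DimensionError("gamma must be a vector (diagonal) or diagonal matrix")
    if np.any(gamma < 0):
        raise DimensionError("gamma entries must be non-negative")
    return gamma


def make_system(
    J: np.ndarray,
    rho: np.ndarray,
    gamma: np.ndarray,
    partition: Partition,
    structure: str = "unconstrained",
    seed: int | None = None,
    circular_direction: str = "ysxa",
    structure_tol: float = 0.0,
) -> PartitionedLinearSystem:
    """Validate and wrap a partitioned linear system.

    Raises :class:`DimensionError` on shape mismatch, :class:`StabilityError`
    if J is not Hurwitz, and :class:`StructureError` if the claimed structure
    mask is violated beyond ``structure_tol``.
    """
    n = partition.n
    J = np.asarray(J, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if J.shape != (n, n):
        raise DimensionError(f"J shape {J.shape} != ({n}, {n})")
    if rho.shape != (n,):
        raise DimensionError(f"rho length {rho.shape} != ({n},)")
    gamma_diag = _as_gamma_diagonal(gamma, n)
    if not is_hurwitz(J):
        raise StabilityError(
            "J is not Hurwitz (max Re eigenvalue "
            f"{np.max(np.linalg.eigvals(J).real):.3g} >= 0); no NESS exists"
        )
    system = PartitionedLinearSystem(
        partition=partition,
        J=J,
        rho=rho,
        gamma_diagonal=gamma_diag,
        structure=structure,
        seed=seed,
        circular_direction=circular_direction,
    )
    if structure != "unconstrained":
        if not partition.requires_all_blocks():
            raise DimensionError(
                f"structure {structure!r} requires all four block sizes >= 1"
            )
        report = check_structure(system, structure, tol=structure_tol)
        if not report["verdict"]:
            bad = {k: v for k, v in report["residuals"].items() if v > structure_tol}
            raise StructureError(
                f"coupling matrix violates the {structure!r} mask: {bad}"
            )
    return system


def check_structure(
    system: PartitionedLinearSystem,
    structure: str | None = None,
    tol: float = 0.0,
) -> dict:
    """Per-block residuals of a structure mask and a pass/fail verdict.

    Returns a dict with ``residuals`` mapping block labels (``"yx"`` for a
    zero-block, ``"ys~sy"`` for a symmetry pair) to Frobenius norms, and
    ``verdict`` = True when every residual is <= ``tol``.
    """
    structure = system.structure if structure is None else structure
    mask = structure_mask(structure, system.circular_direction)
    C = system.C
    p = system.partition
    residuals: dict[str, float] = {}
    for (r, c) in sorted(mask.zero_blocks):
        residuals[f"{r}{c}"] = float(np.linalg.norm(p.block(C, r, c)))
    for ((i, j), (k, l)) in sorted(mask.symmetric_pairs):
        diff = p.block(C, i, j) - p.block(C, k, l).T
        residuals[f"{i}{j}~{k}{l}"] = float(np.linalg.norm(diff))
    verdict = all(v <= tol for v in residuals.values())
    return {"structure": structure, "residuals": residuals, "verdict": verdict}


def _masked_sign_coupling(
    rng: np.random.Generator,
    partition: Partition,
    mask: StructureMask,
) -> np.ndarray:
    """Draw a Rademacher sign pattern and apply a structure mask.

    The full n x n sign matrix is drawn first so the pattern depends only on
    the seed (matched-seed epsilon sweeps scale the same pattern).
    """
    n = partition.n
    signs = rng.choice([-1.0, 1.0], size=(n, n))
    sl = partition.slices
    for (r, c) in mask.zero_blocks:
        signs[sl[r], sl[c]] = 0.0
    for ((i, j), (k, l)) in sorted(mask.symmetric_pairs):
        signs[sl[k], sl[l]] = signs[sl[i], sl[j]].T
    return signs


def generate_random_system(
    structure: str,
    partition: Partition,
    epsilon: float = 0.1,
    sigma: float = 0.1,
    seed: int | None = None,
    max_retries: int = 50,
    circular_direction: str = "ysxa",
) -> PartitionedLinearSystem:
    """Generate a random system with Rademacher couplings C_ij = +/-epsilon.

    Entries of C allowed by the structure mask are epsilon times independent
    random signs (within-block diagonal included); symmetric pairs are drawn
    once and mirrored; masked blocks are exactly zero.  J = -I + epsilon*signs,
    Gamma = sigma^2 I, rho = 0.  The drift is verified Hurwitz, resampling up
    to ``max_retries`` times (never needed at the weak couplings studied here).
    """
    if epsilon < 0 or sigma < 0:
        raise ValueError("epsilon and sigma must be non-negative")
    if structure != "unconstrained" and not partition.requires_all_blocks():
        raise DimensionError(f"structure {structure!r} requires all block sizes >= 1")
    mask = structure_mask(structure, circular_direction)
    rng = np.random.default_rng(seed)
    n = partition.n
    retries = 0
    for _ in range(max_retries + 1):
        signs = _masked_sign_coupling(rng, partition, mask)
        J = -np.eye(n) + epsilon * signs
        if is_hurwitz(J):
            return PartitionedLinearSystem(
                partition=partition,
                J=J,
                rho=np.zeros(n),
                gamma_diagonal=np.full(n, sigma**2),
                structure=structure,
                seed=seed,
                circular_direction=circular_direction,
                extra={"retries": retries},
            )
        retries += 1
    raise GenerationError(
        f"failed to draw a Hurwitz J in {max_retries + 1} attempts "
        f"(epsilon={epsilon} is likely too large)"
    )


def write_system(system: PartitionedLinearSystem, path: str | Path) -> None:
    """Serialize a system to JSON (schema documented in the README)."""
    doc = {
        "version": SCHEMA_VERSION,
        "structure": system.structure,
        "seed": system.seed,
        "circular_direction": system.circular_direction,
        "partition": {
            "ny": system.partition.ny,
            "ns": system.partition.ns,
            "na": system.partition.na,
            "nx": system.partition.nx,
        },
        "J": system.J.tolist(),
        "rho": system.rho.tolist(),
        "gamma_diagonal": system.gamma_diagonal.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_system(path: str | Path) -> PartitionedLinearSystem:
    """Load a system from JSON; unknown extra fields are ignored."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed JSON in {path}: {exc}") from exc
    required = {"version", "structure", "partition", "J", "rho", "gamma_diagonal"}
    missing = required - set(doc)
    if missing:
        raise SchemaError(f"system document missing fields: {sorted(missing)}")
    pdoc = doc["partition"]
    try:
        partition = Partition(
            ny=int(pdoc["ny"]), ns=int(pdoc["ns"]), na=int(pdoc["na"]), nx=int(pdoc["nx"])
        )
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed partition field: {exc}") from exc
    return make_system(
        J=np.asarray(doc["J"], dtype=float),
        rho=np.asarray(doc["rho"], dtype=float),
        gamma=np.asarray(doc["gamma_diagonal"], dtype=float),
        partition=partition,
        structure=doc["structure"],
        seed=doc.get("seed"),
        circular_direction=doc.get("circular_direction", "ysxa"),
    )
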