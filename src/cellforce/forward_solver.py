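"""Semi-implicit solver for the forced, volume-constrained Allen-Cahn equation.

Dimensionless form integrated here (unit square, homogeneous Neumann):

.. math::

    \\bar\\epsilon \\bar\\tau\\, \\partial_{\\bar t} \\phi
        = \\bar\\delta \\bar\\epsilon \\Delta \\phi
        - \\frac{\\bar\\delta}{\\bar\\epsilon} G'(\\phi)
        + \\bar\\eta + \\lambda .

Time stepping is IMEX: the stiff Laplacian is implicit (a direct spectral
solve in the DCT-I eigenbasis of the reflected-ghost Neumann stencil), the
potential derivative and control are explicit.
The mass constraint is enforced after each step by adding the spatial
constant that makes ``mean(phi)`` hit the prescribed target, which is the
discrete Lagrange-multiplier update: the Neumann Laplacian annihilates
constants, so the shift is exactly the action of a constant lambda over the
step, with ``lambda = eps_bar * tau_bar * shift / dt``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.sparse as sp

from .model_core import DimensionlessParams, GridSpec, double_well_deriv

__all__ = [
    "PhaseField",
    "ControlField",
    "MassTarget",
    "StateTrajectory",
    "laplacian_neumann",
    "laplacian_matrix",
    "step",
    "solve_forward",
    "SolverError",
]


class SolverError(RuntimeError):
    """Raised when a linear solve fails or the state becomes non-finite."""


@dataclass
class PhaseField:
    """A 2D phase field sampled on GridSpec nodes at one dimensionless time."""

    values: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("phase field must be a square 2D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phase field contains non-finite values")

    @property
    def mass(self) -> float:
        return float(self.values.mean())


@dataclass
class ControlField:
    """Per-step membrane forcing fields with their interfacial support masks.

    ``values[k]`` is the nodal control applied during step k; it is zero
    wherever ``support_mask[k]`` is False (the force is exerted only in a
    band around the membrane, where the actin cortex acts).
    """

    values: np.ndarray  # (n_steps, n, n)
    support_mask: np.ndarray  # (n_steps, n, n) bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.support_mask = np.asarray(self.support_mask, dtype=bool)
        if self.values.shape != self.support_mask.shape or self.values.ndim != 3:
            raise ValueError("control values and masks must share a (steps, n, n) shape")
        self.values = np.where(self.support_mask, self.values, 0.0)

    @classmethod
    def zeros(cls, n_steps: int, grid: GridSpec, mask: np.ndarray | None = None) -> "ControlField":
        full = np.ones((n_steps,) + grid.shape, dtype=bool) if mask is None else np.broadcast_to(mask, (n_steps,) + grid.shape).copy()
        return cls(np.zeros((n_steps,) + grid.shape), full)

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]


@dataclass
class MassTarget:
    """Prescribed mean of phi at the end of each solver step.

    Differs from mass conservation: consecutive observations may have
    different segmented cell area, so the target interpolates between them.
    """

    values: np.ndarray  # (n_steps,)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("mass target must be a 1D per-step array")
        if np.any(np.abs(self.values) > 1.0 + 1e-9):
            raise ValueError("mean of phi must lie in [-1, 1]")

    @classmethod
    def linear(cls, m0: float, m1: float, n_steps: int) -> "MassTarget":
        """Piecewise-linear ramp from mass m0 (initial) to m1 over n_steps."""
        return cls(np.linspace(m0, m1, n_steps + 1)[1:])


@dataclass
class StateTrajectory:
    """Stored forward solve: states phi^0..phi^N, multipliers, step size.

    ``stride`` > 1 means only every stride-th state was kept (long benchmark
    runs); the solver still took every step and ``lambdas`` is per solver
    step.  ``dt`` is the solver step; stored states are ``stride * dt``
    apart.
    """

    states: np.ndarray  # (n_stored, n, n)
    lambdas: np.ndarray  # (n_solver_steps,)
    dt: float
    t0: float = 0.0
    stride: int = 1

    @property
    def n_steps(self) -> int:
        return self.states.shape[0] - 1

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * self.stride * np.arange(self.states.shape[0])

    def final(self) -> PhaseField:
        return PhaseField(self.states[-1], time=float(self.times[-1]))


def stable_substeps(params: DimensionlessParams, pair_duration: float, safety: float = 0.5) -> int:
    """Substeps per reconstructed step keeping the explicit G' term stable.

    The explicit potential term is stable for dt <= eps_bar^2 tau_bar /
    delta_bar (G'' is bounded by 2 near the bulk values); ``safety`` leaves
    headroom for the transient overshoot after a forcing kick.
    """
    dt_rts = pair_duration / params.RTS
    dt_max = safety * params.eps_bar**2 * params.tau_bar / params.delta_bar
    return max(1, int(np.ceil(dt_rts / dt_max)))


def laplacian_neumann(field: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Five-point Laplacian with ghost-node reflection at the boundary.

    A constant field maps to exactly zero everywhere, including on the
    boundary, which is what makes the constant-shift mass projection an
    exact Lagrange multiplier.
    """
    field = np.asarray(field, dtype=float)
    if field.shape != grid.shape:
        raise ValueError(f"field shape {field.shape} does not match grid {grid.shape}")
    padded = np.pad(field, 1, mode="reflect")
    h2 = grid.spacing**2
    return (
        padded[:-2, 1:-1] + padded[2:, 1:-1] + padded[1:-1, :-2] + padded[1:-1, 2:]
        - 4.0 * field
    ) / h2


def _d2_1d(n: int, h: float) -> sp.csr_matrix:
    """1D second-difference matrix with reflected ghosts (Neumann)."""
    main = -2.0 * np.ones(n)
    off = np.ones(n - 1)
    m = sp.diags([off, main, off], [-1, 0, 1], format="lil")
    m[0, 1] = 2.0
    m[-1, -2] = 2.0
    return sp.csr_matrix(m) / h**2


def laplacian_matrix(grid: GridSpec) -> sp.csr_matrix:
    """Sparse matrix of :func:`laplacian_neumann` acting on flattened fields."""
    d2 = _d2_1d(grid.n, grid.spacing)
    eye = sp.identity(grid.n, format="csr")
    return (sp.kron(d2, eye) + sp.kron(eye, d2)).tocsr()


@lru_cache(maxsize=32)
def _dct_diagonal(n: int, a: float):
    """Spectral data of A = I - a * Laplacian in the DCT-I eigenbasis.

    The reflected-ghost Neumann stencil is diagonalised exactly by the
    type-I cosine basis cos(pi k i / (n-1)), so the implicit solve is a
    direct spectral solve: no factorisation, no iteration error.
    """
    h = 1.0 / (n - 1)
    eig1 = (2.0 * np.cos(np.pi * np.arange(n) / (n - 1)) - 2.0) / h**2
    diag = 1.0 - a * (eig1[:, None] + eig1[None, :])
    e = np.ones(n)
    e[1:-1] = 2.0
    return diag, np.outer(e, e)


def _solve_implicit(rhs: np.ndarray, grid: GridSpec, a: float, transpose: bool = False) -> np.ndarray:
    """Solve (I - a L) x = rhs (or its exact transpose) via DCT-I.

    The transpose solve is what the discrete adjoint needs: the Neumann
    stencil is not Euclidean-symmetric (boundary rows differ), and the
    gradient check only passes if the backward sweep uses A^T exactly.
    """
    from scipy.fft import dctn, idctn

    diag, e2 = _dct_diagonal(grid.n, float(a))
    if np.any(diag == 0.0):
        raise SolverError("implicit operator is singular for this (grid, dt)")
    if transpose:
        return e2 * idctn(dctn(rhs / e2, type=1) / diag, type=1)
    return dctn(e2 * idctn(rhs, type=1) / diag / e2, type=1)


def step(
    phi_n: np.ndarray,
    eta_n: np.ndarray,
    mass_next: float | None,
    params: DimensionlessParams,
    dt: float,
    grid: GridSpec,
) -> tuple[np.ndarray, float]:
    """One IMEX step; returns (phi_{n+1}, lambda_n).

    Implicit Laplacian, explicit potential and control; then the mean is
    projected onto ``mass_next`` (skipped when ``mass_next`` is None, i.e.
    the unconstrained equation, in which case lambda_n = 0).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    eb, tb, db = params.eps_bar, params.tau_bar, params.delta_bar
    b = dt / (eb * tb)
    with np.errstate(over="ignore", invalid="ignore"):  # blow-up is caught below
        rhs = phi_n + b * (-(db / eb) * double_well_deriv(phi_n) + eta_n)
        phi_star = _solve_implicit(rhs, grid, dt * db / tb)
    if mass_next is None:
        lam = 0.0
        phi_new = phi_star
    else:
        shift = mass_next - phi_star.mean()
        lam = shift * eb * tb / dt
        phi_new = phi_star + shift
    if not np.all(np.isfinite(phi_new)):
        raise SolverError(
            "non-finite state after step (dt too large for the explicit "
            f"potential term? dt={dt:g}, eps_bar={eb:g}, tau_bar={tb:g})"
        )
    return phi_new, lam


def solve_forward(
    phi0: PhaseField | np.ndarray,
    eta: ControlField | np.ndarray,
    mass: MassTarget | np.ndarray | None,
    params: DimensionlessParams,
    dt: float,
    grid: GridSpec | None = None,
    t0: float = 0.0,
    store_every: int = 1,
) -> StateTrajectory:
    """Integrate the forced, volume-constrained equation over n_steps = len(eta).

    ``mass=None`` disables the volume constraint (lambda = 0 throughout),
    which recovers plain forced Allen-Cahn / mean-curvature flow dynamics.
    ``store_every`` keeps only every k-th state (n_steps must be divisible
    by it), for long unforced benchmark runs. Deterministic for fixed inputs.
    """
    phi = phi0.values if isinstance(phi0, PhaseField) else np.asarray(phi0, dtype=float)
    eta_vals = eta.values if isinstance(eta, ControlField) else np.asarray(eta, dtype=float)
    if grid is None:
        grid = GridSpec(n=phi.shape[0])
    n_steps = eta_vals.shape[0]
    mass_vals = None
    if mass is not None:
        mass_vals = mass.values if isinstance(mass, MassTarget) else np.asarray(mass, dtype=float)
        if len(mass_vals) != n_steps:
            raise ValueError("mass target length must equal the number of control steps")
    if store_every < 1 or n_steps % store_every:
        raise ValueError("store_every must divide the number of steps")
    states = np.empty((n_steps // store_every + 1,) + grid.shape)
    lambdas = np.empty(n_steps)
    states[0] = phi
    for k in range(n_steps):
        target = None if mass_vals is None else float(mass_vals[k])
        phi, lambdas[k] = step(phi, eta_vals[k], target, params, dt, grid)
        if (k + 1) % store_every == 0:
            states[(k + 1) // store_every] = phi
    return StateTrajectory(states=states, lambdas=lambdas, dt=dt, t0=t0, stride=store_every)


def ginzburg_landau_energy(phi: np.ndarray, params: DimensionlessParams, grid: GridSpec) -> float:
    """E(phi) = int (delta_bar eps_bar / 2)|grad phi|^2 + (delta_bar/eps_bar) G(phi).

    The unforced, unconstrained flow is the L2 gradient flow of E and must
    decrease it monotonically for sufficiently small dt.
    """
    from .model_core import double_well

    gy, gx = np.gradient(phi, grid.spacing)
    dens = 0.5 * params.delta_bar * params.eps_bar * (gx**2 + gy**2)
    dens += (params.delta_bar / params.eps_bar) * double_well(phi)
    return grid.integrate(dens)
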