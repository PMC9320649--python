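"""Physical and dimensionless parameters of the phase-field cell model.

A migrating cell is represented by a phase field :math:`\\phi(\\bar x, \\bar t)`
on the unit square: :math:`\\phi \\approx +1` in the cell bulk,
:math:`\\approx -1` in the extracellular matrix, and the zero level set is the
cell membrane.  The physical model on :math:`\\Omega = [0, L]^2` is the forced,
volume-constrained Allen-Cahn equation

.. math::

    \\epsilon \\tau\\, \\partial_t \\phi
        = \\delta \\epsilon \\Delta \\phi
        - \\frac{\\delta}{\\epsilon} G'(\\phi) + \\eta + \\lambda,

with homogeneous Neumann boundary conditions, double-well potential
:math:`G(\\phi) = \\tfrac14 (1 - \\phi^2)^2`, membrane force density
:math:`\\eta` (pN/um, positive = protrusion) and a spatially constant
Lagrange multiplier :math:`\\lambda(t)` tracking a prescribed cell mass.

Nondimensionalization uses a characteristic length ``L`` (domain side),
time ``T`` (duration of the tracked experiment) and force ``F``:

.. math::

    \\bar x = x / L, \\quad \\bar\\epsilon = \\epsilon / L, \\quad
    \\bar t = t / T, \\quad \\bar\\eta = \\eta L / F, \\quad
    \\bar\\delta = \\delta / F, \\quad \\bar\\tau = \\tau L^2 / (F T).

This module holds the parameter containers, the potential and its
derivative, the scaling maps, and the equilibrium tanh interface profile
used to build phase-field representations of segmented images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PhysicalParams",
    "DimensionlessParams",
    "GridSpec",
    "double_well",
    "double_well_deriv",
    "double_well_second_deriv",
    "nondimensionalize",
    "redimensionalize_force",
    "tanh_profile",
    "ParameterError",
]


class ParameterError(ValueError):
    """Raised when a physical or numerical parameter is out of range."""


@dataclass(frozen=True)
class PhysicalParams:
    """Dimensional model parameters for one dataset.

    Parameters
    ----------
    delta : float
        Membrane surface tension, pN.  Reported values for migrating cells
        span roughly 1-10 pN.
    tau : float
        Effective friction with the substrate / extracellular matrix,
        pN s / um^2.
    eps : float
        Membrane (interface) thickness, um.
    L : float
        Side length of the square imaging domain, um.
    T_total : float
        Duration of the tracked experiment, s; doubles as the
        characteristic time of the nondimensionalization.
    TI : float
        Time interval between consecutive video frames, s.
    F : float
        Characteristic force used to scale surface tension and the
        recovered membrane force, pN.
    height : float
        Assumed constant cell height used to reduce to two dimensions, um.
    """

    delta: float = 10.0
    tau: float = 2.62
    eps: float = 1.0
    L: float = 100.0
    T_total: float = 600.0
    TI: float = 60.0
    F: float = 10.0
    height: float = 0.1

    def __post_init__(self) -> None:
        for name in ("delta", "tau", "eps", "L", "T_total", "TI", "F", "height"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        if self.TI > self.T_total:
            raise ParameterError("frame interval TI cannot exceed T_total")
        if self.eps >= self.L:
            raise ParameterError("membrane thickness eps must be < domain size L")

    @property
    def n_frame_intervals(self) -> int:
        return int(round(self.T_total / self.TI))


@dataclass(frozen=True)
class DimensionlessParams:
    """Dimensionless parameters actually consumed by the solver.

    ``eps_bar`` is the *numerical* interfacial width: per-dataset configs
    may override the physical ratio eps/L so the interface stays resolved
    on the chosen grid.  ``RTS`` is the number of reconstructed time steps
    inserted between consecutive frames; each may be subdivided into
    ``substeps`` solver steps for stability of the explicit potential term.
    """

    eps_bar: float
    tau_bar: float
    delta_bar: float = 1.0
    theta: float = 1e-3
    RTS: int = 10
    substeps: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.eps_bar <= 0.2:
            raise ParameterError("eps_bar must lie in (0, 0.2]")
        if self.tau_bar <= 0 or self.delta_bar <= 0 or self.theta <= 0:
            raise ParameterError("tau_bar, delta_bar and theta must be > 0")
        if self.RTS < 1 or self.substeps < 1:
            raise ParameterError("RTS and substeps must be integers >= 1")

    def with_(self, **kwargs) -> "DimensionlessParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GridSpec:
    """Uniform vertex-centred grid on the unit square.

    Nodes sit at ``(i*h, j*h)`` with ``h = 1/(n-1)``; the origin is the
    bottom-left corner and y increases upward.  Field arrays are indexed
    ``values[j, i]`` (row = y index).  Boundaries carry homogeneous
    Neumann conditions, discretised by ghost-node reflection.
    """

    n: int = 64

    def __post_init__(self) -> None:
        if self.n < 8:
            raise ParameterError("grid needs at least 8 nodes per side")

    @property
    def spacing(self) -> float:
        return 1.0 / (self.n - 1)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n, self.n)

    @property
    def axis(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n)

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(X, Y)`` coordinate arrays shaped like a field."""
        x = self.axis
        return np.meshgrid(x, x, indexing="xy")

    def quad_weights(self) -> np.ndarray:
        """Trapezoidal quadrature weights; sum to the unit-square area 1."""
        w1 = np.full(self.n, self.spacing)
        w1[0] *= 0.5
        w1[-1] *= 0.5
        return np.outer(w1, w1)

    def integrate(self, values: np.ndarray) -> float:
        return float(np.sum(self.quad_weights() * values))


def double_well(phi):
    """Double-well potential G(phi) = (1 - phi^2)^2 / 4, minima at +-1."""
    return 0.25 * (1.0 - np.asarray(phi) ** 2) ** 2


def double_well_deriv(phi):
    """G'(phi) = phi^3 - phi."""
    phi = np.asarray(phi)
    return phi**3 - phi


def double_well_second_deriv(phi):
    """G''(phi) = 3 phi^2 - 1 (needed by the linearised/adjoint dynamics)."""
    return 3.0 * np.asarray(phi) ** 2 - 1.0


def nondimensionalize(
    p: PhysicalParams,
    eps_bar_override: float | None = None,
    *,
    theta: float = 1e-3,
    RTS: int = 10,
    substeps: int = 1,
) -> DimensionlessParams:
    """Map physical parameters to the dimensionless set used by the solver.

    tau_bar = tau L^2 / (F T), delta_bar = delta / F, eps_bar = eps / L.
    Per-dataset configs typically override eps_bar with a numerical
    interfacial width chosen for the grid rather than the physical ratio.
    """
    eps_bar = p.eps / p.L if eps_bar_override is None else float(eps_bar_override)
    if eps_bar <= 0:
        raise ParameterError("eps_bar override must be > 0")
    return DimensionlessParams(
        eps_bar=eps_bar,
        tau_bar=p.tau * p.L**2 / (p.F * p.T_total),
        delta_bar=p.delta / p.F,
        theta=theta,
        RTS=RTS,
        substeps=substeps,
    )


def redimensionalize_force(eta_bar, p: PhysicalParams):
    """Convert a dimensionless control to a force line density in pN/um.

    Inverse of the scaling eta_bar = eta / (F / L): eta = eta_bar * F / L.
    Accepts scalars or arrays (entire control fields).
    """
    return np.asarray(eta_bar, dtype=float) * (p.F / p.L)


def tanh_profile(signed_distance, eps_bar: float) -> np.ndarray:
    """Equilibrium interface profile phi = tanh(d / (sqrt(2) eps_bar)).

    ``signed_distance`` is positive inside the cell and negative outside,
    in dimensionless units; the zero level set coincides with d = 0.
    This is the standing-wave solution of the quartic double well, used to
    turn segmented masks and analytic shapes into phase fields.
    """
    if eps_bar <= 0:
        raise ParameterError("eps_bar must be > 0")
    return np.tanh(np.asarray(signed_distance, dtype=float) / (np.sqrt(2.0) * eps_bar))
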