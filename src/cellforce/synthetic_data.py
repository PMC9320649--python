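"""Self-contained synthetic fixtures: analytic fields, rendered movies and
forward-model-generated ("inverse crime") target sequences.

These generators emulate the kinds of data the pipeline is built for —
bright cells on a dark background that translate, deform and divide — with
known ground truth, so every downstream stage (segmentation, tracking,
force summaries, cell counting) can be verified end to end.  All of them
are pure functions of their parameters and a single seed.

Default rendering: background 0.2, foreground 0.8, Gaussian noise sigma
0.05, 8-bit quantisation — two well-separated intensity modes that Otsu
splits robustly at contrast/noise = 12, and still splits at the noisier
settings used in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward_solver import ControlField, MassTarget, PhaseField, solve_forward
from .imaging import CellMask, ImageFrame
from .model_core import DimensionlessParams, GridSpec, tanh_profile
from .optimal_control import TargetSequence

__all__ = [
    "RenderOptions",
    "SyntheticMovie",
    "make_disk_field",
    "make_annulus_field",
    "make_blob_field",
    "make_translating_disk_movie",
    "make_division_movie",
    "make_inverse_crime_dataset",
    "make_translating_disk_pair",
    "dipole_control",
]


@dataclass(frozen=True)
class RenderOptions:
    """How ground-truth masks are rendered into grayscale frames."""

    image_size: int = 128
    background: float = 0.2
    foreground: float = 0.8
    noise_sigma: float = 0.05
    quantize: bool = True  # 8-bit like real microscopy exports


@dataclass
class SyntheticMovie:
    """Rendered frames + ground-truth masks + generator metadata."""

    frames: list  # list[ImageFrame]
    masks: list  # list[CellMask]
    meta: dict

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def make_disk_field(
    center: tuple, radius: float, eps_bar: float, grid: GridSpec
) -> PhaseField:
    """Tanh profile of the exact signed distance to a circle."""
    if radius <= 2.0 * eps_bar:
        raise ValueError("radius must exceed 2 * eps_bar to resolve the interface")
    x, y = grid.mesh()
    d = radius - np.hypot(x - center[0], y - center[1])
    return PhaseField(tanh_profile(d, eps_bar))


def make_annulus_field(
    center: tuple, r_outer: float, r_inner: float, eps_bar: float, grid: GridSpec
) -> PhaseField:
    """Tanh annulus: one component, one hole (Euler characteristic 0)."""
    if not r_inner < r_outer:
        raise ValueError("need r_inner < r_outer")
    x, y = grid.mesh()
    r = np.hypot(x - center[0], y - center[1])
    d = np.minimum(r_outer - r, r - r_inner)
    return PhaseField(tanh_profile(d, eps_bar))


def make_blob_field(
    seed: int,
    grid: GridSpec,
    eps_bar: float = 0.02,
    n_blobs_range: tuple = (2, 5),
    with_annulus_prob: float = 0.3,
) -> tuple[PhaseField, int]:
    """Random field of disjoint disks (sometimes one annulus) and its true chi.

    Disks are rejection-sampled to keep at least 4*eps_bar of clearance from
    each other and the boundary; annulus rings are wide enough that the
    phase field saturates to +1 inside the ring (a ring thinner than the
    full tanh transition never leaves the |phi| < c band, which breaks the
    band-integral assumption of the diffuse Euler number).  chi = number of
    disks; an annulus contributes 0.
    """
    rng = np.random.default_rng(seed)
    n_blobs = int(rng.integers(n_blobs_range[0], n_blobs_range[1] + 1))
    shapes = []  # (cx, cy, r_outer, r_inner or None)
    attempts = 0
    while len(shapes) < n_blobs and attempts < 500:
        attempts += 1
        inner = None
        if rng.random() < with_annulus_prob and not any(s[3] for s in shapes):
            r = rng.uniform(0.16, 0.18)
            inner = rng.uniform(2.5 * eps_bar, r - 5.5 * eps_bar)
        else:
            r = rng.uniform(0.09, 0.14)
        c = rng.uniform(r + 4 * eps_bar, 1 - r - 4 * eps_bar, size=2)
        if all(np.hypot(c[0] - s[0], c[1] - s[1]) > r + s[2] + 4 * eps_bar for s in shapes):
            shapes.append((c[0], c[1], r, inner))
    x, y = grid.mesh()
    d = np.full(grid.shape, -np.inf)
    chi = 0
    for cx, cy, r, inner in shapes:
        rr = np.hypot(x - cx, y - cy)
        di = r - rr if inner is None else np.minimum(r - rr, rr - inner)
        d = np.maximum(d, di)
        chi += 1 if inner is None else 0
    return PhaseField(tanh_profile(d, eps_bar)), chi


def _render(mask: np.ndarray, opts: RenderOptions, rng: np.random.Generator) -> np.ndarray:
    img = np.where(mask, opts.foreground, opts.background)
    img = img + rng.normal(0.0, opts.noise_sigma, size=img.shape)
    if opts.quantize:
        img = np.round(np.clip(img, 0.0, 1.0) * 255.0) / 255.0
    return img


def _pixel_mesh(size: int) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-vertex coordinates on the unit square, image row 0 at the top."""
    u = np.linspace(0.0, 1.0, size)
    x, y = np.meshgrid(u, u[::-1], indexing="xy")
    return x, y


def make_translating_disk_movie(
    velocity: tuple = (0.3, 0.0),
    n_frames: int = 5,
    radius: float = 0.2,
    start: tuple = (0.3, 0.5),
    render: RenderOptions | None = None,
    seed: int = 0,
    frame_dt: float | None = None,
) -> SyntheticMovie:
    """Movie of a rigid disk advancing by v * dt_frame per frame.

    Masks are exact disk indicators (area-constant); frames are the seeded
    noisy renders.  The disk must stay inside the unit square.
    """
    render = render or RenderOptions()
    dt_frame = 1.0 / (n_frames - 1) if frame_dt is None else frame_dt
    rng = np.random.default_rng(seed)
    x, y = _pixel_mesh(render.image_size)
    px = 1.0 / (render.image_size - 1)
    frames, masks = [], []
    centers = []
    for i in range(n_frames):
        c = (start[0] + velocity[0] * dt_frame * i, start[1] + velocity[1] * dt_frame * i)
        if not (radius <= c[0] <= 1 - radius and radius <= c[1] <= 1 - radius):
            raise ValueError(f"disk leaves the domain at frame {i}")
        centers.append(c)
        mask = np.hypot(x - c[0], y - c[1]) <= radius
        masks.append(CellMask(mask))
        frames.append(ImageFrame(_render(mask, render, rng), pixel_size=px, index=i, timestamp=i * dt_frame))
    meta = {
        "generator": "translating_disk",
        "velocity": list(velocity),
        "radius": radius,
        "centers": centers,
        "seed": seed,
        "frame_dt": dt_frame,
    }
    return SyntheticMovie(frames=frames, masks=masks, meta=meta)


def make_division_movie(
    n_frames: int = 9,
    max_separation: float = 0.4,
    radius: float = 0.105,
    center: tuple = (0.5, 0.5),
    axis_angle: float = 0.0,
    n_cells: int = 1,
    render: RenderOptions | None = None,
    seed: int = 0,
) -> SyntheticMovie:
    """One blob (two overlapping disks) pinching into two disjoint disks.

    The two half-disks separate linearly from 0 to ``max_separation``.
    ``meta['division_frame']`` records the first frame whose ground-truth
    mask actually splits into two components — the observable division
    event (the analytic tangency can fall between frames or below pixel
    resolution).  The defaults keep every frame's geometry decisive: at the
    last connected frame the neck is several pixels wide, at the first
    divided frame the gap is several pixels wide.

    ``n_cells = 3`` replicates the event at three well-separated locations
    (a synthetic analogue of divisions in a small epithelial patch): every
    blob divides at the same frame and the component count jumps from 3
    to 6.
    """
    render = render or RenderOptions()
    rng = np.random.default_rng(seed)
    x, y = _pixel_mesh(render.image_size)
    px = 1.0 / (render.image_size - 1)
    if max_separation <= 2 * radius:
        raise ValueError("max_separation must exceed the disk diameter for a division")
    if n_cells == 1:
        cell_centers = [center]
        angles = [axis_angle]
    elif n_cells == 3:
        cell_centers = [(0.3, 0.25), (0.75, 0.3), (0.45, 0.75)]
        angles = [axis_angle, axis_angle + np.pi / 2, axis_angle]
    else:
        raise ValueError("n_cells must be 1 or 3")
    seps = np.linspace(0.0, max_separation, n_frames)
    frames, masks = [], []
    division_frame = None
    from scipy import ndimage

    for i, s in enumerate(seps):
        mask = np.zeros_like(x, dtype=bool)
        for (cx, cy), ang in zip(cell_centers, angles):
            ux, uy = np.cos(ang), np.sin(ang)
            for sgn in (-1.0, 1.0):
                dx, dy = sgn * 0.5 * s * ux, sgn * 0.5 * s * uy
                mask |= np.hypot(x - cx - dx, y - cy - dy) <= radius
        n_comp = int(ndimage.label(mask, structure=np.ones((3, 3)))[1])
        if division_frame is None and n_comp == 2 * n_cells:
            division_frame = i
        masks.append(CellMask(mask))
        frames.append(ImageFrame(_render(mask, render, rng), pixel_size=px, index=i, timestamp=float(i)))
    meta = {
        "generator": "division",
        "n_cells": n_cells,
        "radius": radius,
        "max_separation": max_separation,
        "division_frame": division_frame,
        "seed": seed,
    }
    return SyntheticMovie(frames=frames, masks=masks, meta=meta)


def dipole_control(
    phi: np.ndarray | PhaseField,
    amplitude: float,
    grid: GridSpec,
    band_level: float = 0.95,
    direction: float = 0.0,
) -> np.ndarray:
    """A protrusion/retraction dipole on the interfacial band of ``phi``.

    eta = amplitude * cos(angle - direction) about the cell centroid:
    positive (protrusive) on the leading edge, negative (retractive) at the
    rear, which is the canonical polarised-migration force pattern.
    """
    from .geometry import centroid

    vals = phi.values if isinstance(phi, PhaseField) else np.asarray(phi, dtype=float)
    cx, cy = centroid(vals, grid)
    x, y = grid.mesh()
    angle = np.arctan2(y - cy, x - cx)
    band = np.abs(vals) < band_level
    return np.where(band, amplitude * np.cos(angle - direction), 0.0)


def make_inverse_crime_dataset(
    eta_star: ControlField | np.ndarray,
    phi0: PhaseField | np.ndarray,
    params: DimensionlessParams,
    duration: float = 1.0,
    n_obs: int = 1,
    mass: MassTarget | np.ndarray | None = "auto",
    grid: GridSpec | None = None,
) -> tuple[TargetSequence, dict]:
    """Generate targets by running the forward model with a known control.

    The returned observations are exact solver states at the n_obs frame
    times, so the subsequent fit commits the classic (and here deliberate)
    inverse crime: the data are consistent with the model by construction
    and the optimiser's only job is to recover the forcing.  ``mass="auto"``
    holds the initial mass constant; ``None`` disables the constraint.
    """
    phi0_vals = phi0.values if isinstance(phi0, PhaseField) else np.asarray(phi0, dtype=float)
    eta_vals = eta_star.values if isinstance(eta_star, ControlField) else np.asarray(eta_star, dtype=float)
    if grid is None:
        grid = GridSpec(n=phi0_vals.shape[0])
    n_steps = eta_vals.shape[0]
    if n_steps % n_obs:
        raise ValueError("n_obs must divide the number of control steps")
    if isinstance(mass, str) and mass == "auto":
        mass = np.full(n_steps, float(phi0_vals.mean()))
    dt = duration / n_steps
    traj = solve_forward(phi0_vals, eta_vals, mass, params, dt, grid)
    stride = n_steps // n_obs
    obs = traj.states[stride::stride]
    times = dt * stride * np.arange(1, n_obs + 1)
    truth = {"eta_star": eta_vals, "trajectory": traj, "mass": mass, "dt": dt}
    return TargetSequence(obs, times), truth


def make_translating_disk_pair(
    grid: GridSpec,
    params: DimensionlessParams,
    amplitude: float = 10.0,
    duration: float = 0.1,
    radius: float = 0.25,
    center: tuple = (0.4, 0.5),
) -> tuple[PhaseField, TargetSequence, np.ndarray]:
    """Standard inverse-crime fixture: a disk pushed rightward by a dipole.

    Returns (phi0, one-frame target sequence, the true per-step control).
    The dipole sits on the initial interfacial band and is constant in
    time; the volume constraint holds the initial mass, so the target is a
    translated (not shrunk) cell.
    """
    phi0 = make_disk_field(center, radius, params.eps_bar, grid)
    n_steps = params.RTS * params.substeps
    eta0 = dipole_control(phi0, amplitude, grid)
    eta = np.broadcast_to(eta0, (n_steps,) + grid.shape).copy()
    targets, truth = make_inverse_crime_dataset(
        eta, phi0, params, duration=duration, n_obs=1, grid=grid
    )
    return phi0, targets, truth["eta_star"]
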