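"""From microscopy frames to phase-field observations.

Segmentation combines Otsu thresholding with gradient-magnitude edge
detection, followed by hole filling and small-component removal.  The mask
is then converted to a phase field: signed Euclidean distance (positive
inside the cell), rescaled to dimensionless units, resampled onto the
solver grid and passed through the equilibrium tanh profile.

Coordinate convention: image row 0 is the top of the picture (raster
order), while solver fields have y increasing upward with row 0 at the
bottom; ingestion flips rows exactly once, in :func:`mask_to_phasefield`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, morphology

from .forward_solver import PhaseField
from .model_core import GridSpec, tanh_profile
from .optimal_control import TargetSequence

__all__ = [
    "ImageFrame",
    "CellMask",
    "SegmentationConfig",
    "NoCellError",
    "segment",
    "mask_to_phasefield",
    "frames_to_targets",
]


class NoCellError(ValueError):
    """Segmentation could not find any cell in a frame."""


@dataclass
class ImageFrame:
    """One grayscale microscopy frame with its physical pixel size."""

    pixels: np.ndarray
    pixel_size: float  # um per pixel
    index: int = 0
    timestamp: float = 0.0  # seconds

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("frame must be a 2D grayscale array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("frame contains non-finite intensities")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class CellMask:
    """Boolean cell mask plus its labelled connected components."""

    values: np.ndarray
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.labels is None:
            self.labels, _ = ndimage.label(self.values)

    @property
    def n_components(self) -> int:
        return int(self.labels.max())

    @property
    def areas(self) -> np.ndarray:
        return np.bincount(self.labels.ravel())[1:]


@dataclass
class SegmentationConfig:
    """Tunables of the Otsu + edge-detection pipeline.

    ``bright_cells`` selects polarity (cells brighter than background by
    default).  The edge map is the Sobel gradient magnitude thresholded at
    ``edge_percentile`` and closed with a disk of ``closing_radius`` pixels;
    components smaller than ``min_area`` pixels are dropped.
    """

    bright_cells: bool = True
    presmooth_sigma: float = 1.5
    edge_percentile: float = 90.0
    closing_radius: int = 3
    shrink_radius: int = 4  # erode the edge-fill term inside the Otsu boundary
    min_area: int = 50
    crop: tuple | None = None  # (row0, row1, col0, col1) optional field of view


def segment(frame: ImageFrame, cfg: SegmentationConfig | None = None) -> CellMask:
    """Segment one frame into a cell mask (deterministic).

    Gaussian presmooth -> Otsu threshold (the core mask, whose boundary sits
    at the half-contrast level and is sub-pixel accurate) -> augment with
    the hole-filled union of core and the closed gradient-magnitude edge
    map, eroded by ``shrink_radius`` to undo the outward bias of the edge
    band -> fill holes -> drop small components.  The edge term only adds
    regions whose interior the intensity threshold missed; where Otsu is
    reliable the boundary is the Otsu boundary.  Raises
    :class:`NoCellError` on a constant image or when nothing survives the
    area filter.
    """
    cfg = cfg or SegmentationConfig()
    img = frame.pixels
    if cfg.crop is not None:
        r0, r1, c0, c1 = cfg.crop
        img = img[r0:r1, c0:c1]
    if img.max() == img.min():
        raise NoCellError(f"frame {frame.index}: constant intensity, Otsu undefined")
    smooth = filters.gaussian(img, sigma=cfg.presmooth_sigma, preserve_range=True)
    thr = filters.threshold_otsu(smooth)
    core = smooth > thr if cfg.bright_cells else smooth < thr
    grad = filters.sobel(smooth)
    # percentile threshold, floored at a fraction of the peak gradient: in a
    # clean image most gradients vanish and the bare percentile would mark
    # wide bands of numerically tiny "edges"
    edges = grad > max(np.percentile(grad, cfg.edge_percentile), 0.1 * grad.max())
    edges = morphology.closing(edges, morphology.disk(cfg.closing_radius))
    edge_fill = ndimage.binary_fill_holes(core | edges)
    if cfg.shrink_radius > 0:
        edge_fill = morphology.erosion(edge_fill, morphology.disk(cfg.shrink_radius))
    mask = ndimage.binary_fill_holes(core | edge_fill)
    # drop components strictly smaller than min_area pixels
    labels, _ = ndimage.label(mask)
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    mask = areas[labels] >= cfg.min_area
    if not mask.any():
        raise NoCellError(f"frame {frame.index}: no component >= {cfg.min_area} px")
    return CellMask(mask)


def signed_distance(mask: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance in pixels, positive inside the mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.all() or not mask.any():
        sign = 1.0 if mask.all() else -1.0
        return np.full(mask.shape, sign * max(mask.shape))
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return inside - outside


def mask_to_phasefield(
    mask: CellMask | np.ndarray,
    grid: GridSpec,
    eps_bar: float,
    pixel_size: float | None = None,
    L: float | None = None,
) -> PhaseField:
    """Phase-field representation of a segmented mask on the solver grid.

    The signed pixel distance is rescaled to unit-square coordinates
    (``pixel_size / L``; if either is omitted the mask is assumed to span
    the whole domain), bilinearly resampled onto grid nodes with the raster
    row order flipped so y increases upward, then mapped through the tanh
    profile.  An empty mask gives phi ~ -1 everywhere, with a warning.
    """
    m = mask.values if isinstance(mask, CellMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        warnings.warn("empty mask: returning a cell-free phase field", stacklevel=2)
        return PhaseField(np.full(grid.shape, -1.0))
    d_px = signed_distance(m)
    n_rows, n_cols = m.shape
    if pixel_size is not None and L is not None:
        scale = pixel_size / L
    else:
        scale = 1.0 / max(n_rows - 1, n_cols - 1)
    d_bar = d_px[::-1, :] * scale  # flip: image row 0 (top) -> high y
    # map grid nodes into (flipped) pixel index coordinates
    x = grid.axis / scale
    rows, cols = np.meshgrid(x, x, indexing="ij")
    sampled = ndimage.map_coordinates(d_bar, [rows, cols], order=1, mode="nearest")
    return PhaseField(tanh_profile(sampled, eps_bar))


def frames_to_targets(
    frames: list,
    grid: GridSpec,
    eps_bar: float,
    T_total: float,
    TI: float,
    L: float | None = None,
    cfg: SegmentationConfig | None = None,
) -> tuple[PhaseField, TargetSequence]:
    """Turn a frame sequence into (initial condition, target sequence).

    The first frame becomes phi0; frames 2..N become observations at
    dimensionless times i * TI / T_total with their masses recorded from
    each observation field.  Segmentation failures name the frame.
    """
    if len(frames) < 2:
        raise ValueError("need at least two frames (one initial + one target)")
    fields = []
    for fr in frames:
        try:
            m = segment(fr, cfg)
        except NoCellError as exc:
            raise NoCellError(f"frame {fr.index}: {exc}") from exc
        fields.append(
            mask_to_phasefield(m, grid, eps_bar, pixel_size=fr.pixel_size, L=L).values
        )
    times = np.arange(1, len(frames)) * TI / T_total
    return PhaseField(fields[0]), TargetSequence(np.stack(fields[1:]), times)
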