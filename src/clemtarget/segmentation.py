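"""Feature segmentation: vessel/tissue masks and surface point clouds.

The vessel network visible in both modalities is the 3D roadmap that the
registration runs on.  Segmentation here is deliberately simple — Gaussian
smoothing, global thresholding, small-component removal — mirroring a
threshold-based interactive workflow; masks the operator corrected by hand
can equally be supplied as files.  In microCT the vessels appear *darker*
than the stained tissue (lower density), hence the ``invert`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label

from .volumes import Volume

__all__ = ["Mask", "PointSet", "segment_features", "mask_surface_points"]


@dataclass
class Mask:
    """Boolean grid sharing shape/spacing/origin/frame with its source Volume."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    frame: str = "ivm"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        self.origin = tuple(float(o) for o in self.origin)

    def count(self) -> int:
        return int(self.voxels.sum())


@dataclass
class PointSet:
    """N physical points (µm) in one frame, with optional per-point weights."""

    points: np.ndarray
    frame: str = "ivm"
    weight: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points must be finite")
        if self.weight is not None:
            self.weight = np.asarray(self.weight, dtype=float).reshape(-1)
            if len(self.weight) != len(self.points):
                raise ValueError("weight length mismatch")

    def __len__(self) -> int:
        return len(self.points)


class SegmentationError(RuntimeError):
    """A segmentation stage produced an empty (or full) mask."""


def _resolve_threshold(smoothed: np.ndarray, threshold) -> float:
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold method {threshold!r}")
        try:
            return float(threshold_otsu(smoothed))
        except ValueError as e:  # constant image
            raise SegmentationError(f"otsu threshold failed: {e}") from e
    if isinstance(threshold, tuple) and threshold[0] == "quantile":
        return float(np.quantile(smoothed, threshold[1]))
    return float(threshold)


def segment_features(
    volume: Volume,
    sigma: float = 1.0,
    threshold="otsu",
    min_component: int = 0,
    invert: bool = False,
) -> Mask:
    """Gaussian-smooth, threshold, and clean a feature mask.

    Parameters
    ----------
    sigma : float
        Smoothing SD in physical µm (converted per-axis to voxels).
    threshold : "otsu" | float | ("quantile", q)
        Global threshold rule applied to the smoothed volume; voxels strictly
        above it are foreground.
    min_component : int
        Connected components (26-connectivity) smaller than this many voxels
        are removed.
    invert : bool
        Negate intensities first, for features darker than background
        (vessels in microCT).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    data = volume.voxels.astype(float)
    if invert:
        data = data.max() - data
    if sigma > 0:
        sx, sy, sz = volume.spacing
        data = ndimage.gaussian_filter(data, sigma=(sigma / sz, sigma / sy, sigma / sx))
    thr = _resolve_threshold(data, threshold)
    mask = data > thr
    if not mask.any() or mask.all():
        raise SegmentationError(
            "thresholding produced an empty or full mask "
            f"(threshold={threshold!r} -> {thr:.4g})"
        )
    if min_component > 0:
        lbl = label(mask, connectivity=3)  # 26-connectivity in 3D
        counts = np.bincount(lbl.ravel())
        keep = counts >= min_component
        keep[0] = False
        mask = keep[lbl]
        if not mask.any():
            raise SegmentationError(
                f"component filtering (min_component={min_component}) emptied the mask"
            )
    return Mask(mask, volume.spacing, volume.origin, volume.frame)


def mask_surface_points(mask: Mask, max_points: int | None = None, seed: int = 0) -> PointSet:
    """Surface voxel centers of a mask, optionally subsampled.

    A surface voxel has at least one background 6-neighbor (voxels at the
    grid boundary count as surface).  If more than ``max_points`` surface
    voxels exist, a uniform random subsample reproducible per ``seed`` is
    returned.  Points are voxel-center physical coordinates.
    """
    if not mask.voxels.any():
        raise SegmentationError("empty mask")
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    eroded = ndimage.binary_erosion(mask.voxels, structure=structure, border_value=0)
    surface = mask.voxels & ~eroded
    kji = np.argwhere(surface).astype(float)
    sx, sy, sz = mask.spacing
    ox, oy, oz = mask.origin
    pts = np.column_stack(
        [ox + kji[:, 2] * sx, oy + kji[:, 1] * sy, oz + kji[:, 0] * sz]
    )
    if max_points is not None and len(pts) > max_points:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pts), size=max_points, replace=False)
        pts = pts[np.sort(idx)]
    return PointSet(pts, frame=mask.frame)
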