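"""Target prediction in the resin-block frame: block faces and distances.

After registration the target cell's intravital coordinates can be mapped
into the microCT frame of the resin-embedded sample.  The trimmed block
faces (front face, cut by the ultramicrotome, and the flank, exposed to the
ion beam) are modeled as planes fit to operator-segmented face patches of
the microCT surface; the prediction reports the signed distances of the
mapped target to those faces, which directly drive the trim plan.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .registration import RegistrationReport
from .segmentation import PointSet
from .volumes import Plane

__all__ = [
    "BlockModel",
    "TargetPrediction",
    "fit_plane",
    "build_block_model",
    "predict_target",
]

# trimmed faces are approximately perpendicular; |cos| thresholds
_PERP_WARN = 0.05
_PERP_ERROR = 0.3


@dataclass
class BlockModel:
    """Planar faces of the trimmed resin block (microCT frame)."""

    front_face: Plane
    flank: Plane
    other_faces: list[Plane] = field(default_factory=list)
    frame: str = "microct"

    def __post_init__(self) -> None:
        cos = abs(float(self.front_face.normal @ self.flank.normal))
        if cos > _PERP_ERROR:
            raise ValueError(
                f"front/flank faces are far from perpendicular (|cos|={cos:.3f})"
            )
        if cos > _PERP_WARN:
            warnings.warn(
                f"front/flank faces deviate from perpendicular (|cos|={cos:.3f})",
                UserWarning,
                stacklevel=2,
            )

    def to_dict(self) -> dict:
        return {
            "front_face": self.front_face.to_dict(),
            "flank": self.flank.to_dict(),
            "other_faces": [p.to_dict() for p in self.other_faces],
            "frame": self.frame,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BlockModel":
        return cls(
            Plane.from_dict(d["front_face"]),
            Plane.from_dict(d["flank"]),
            [Plane.from_dict(p) for p in d.get("other_faces", [])],
            d.get("frame", "microct"),
        )


@dataclass
class TargetPrediction:
    """Predicted target position and its distances to the block faces.

    Signed distances use the outward normals, so a target inside the block
    has negative signed distance; the reported ``distance_to_*`` fields are
    the magnitudes the microtomist trims against.
    """

    position: np.ndarray
    distance_to_front: float
    distance_to_flank: float
    tre_estimate: float
    transform_report: RegistrationReport | None = None
    inside_block: bool = True
    signed_distance_to_front: float = 0.0
    signed_distance_to_flank: float = 0.0

    def to_dict(self) -> dict:
        return {
            "position_um": np.asarray(self.position).tolist(),
            "distance_to_front_um": self.distance_to_front,
            "distance_to_flank_um": self.distance_to_flank,
            "tre_estimate_um": self.tre_estimate,
            "inside_block": self.inside_block,
        }

    def save(self, path) -> Path:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))
        return Path(path)


def fit_plane(points: PointSet, interior_point=None) -> Plane:
    """Total-least-squares plane through a point cloud.

    The plane passes through the centroid with the smallest-variance
    principal direction as normal.  If ``interior_point`` (a point inside
    the block) is given, the normal is oriented away from it (outward).
    """
    pts = points.points
    if len(pts) < 3:
        raise ValueError("plane fit needs >= 3 points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, sv, Vt = np.linalg.svd(centered, full_matrices=False)
    tol = max(pts.shape) * np.finfo(float).eps * sv[0] if sv[0] > 0 else 0.0
    if sv[1] <= tol:
        raise ValueError("points are collinear; plane is underdetermined")
    normal = Vt[2]
    if interior_point is not None:
        interior_point = np.asarray(interior_point, dtype=float)
        if normal @ (centroid - interior_point) < 0:
            normal = -normal
    return Plane(centroid, normal / np.linalg.norm(normal))


def build_block_model(
    front_points: PointSet, flank_points: PointSet, interior_point
) -> BlockModel:
    """Fit front and flank planes, oriented outward from an interior point."""
    front = fit_plane(front_points, interior_point=interior_point)
    flank = fit_plane(flank_points, interior_point=interior_point)
    return BlockModel(front, flank)


def predict_target(
    target_ivm,
    transform,
    block: BlockModel,
    report: RegistrationReport | None = None,
) -> TargetPrediction:
    """Map the intravital target into the block and measure face distances."""
    target_ivm = np.asarray(target_ivm, dtype=float).reshape(3)
    position = np.asarray(transform.transform_points(target_ivm)).reshape(3)
    sd_front = float(block.front_face.signed_distance(position[None])[0])
    sd_flank = float(block.flank.signed_distance(position[None])[0])
    inside = sd_front <= 0 and sd_flank <= 0
    if not inside:
        warnings.warn(
            "predicted target lies outside the block "
            f"(signed distances front={sd_front:.2f} µm, flank={sd_flank:.2f} µm)",
            UserWarning,
            stacklevel=2,
        )
    return TargetPrediction(
        position=position,
        distance_to_front=abs(sd_front),
        distance_to_flank=abs(sd_flank),
        tre_estimate=report.loo_tre_rms if report is not None else 0.0,
        transform_report=report,
        inside_block=inside,
        signed_distance_to_front=sd_front,
        signed_distance_to_flank=sd_flank,
    )
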