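"""Synthetic matched IVM/microCT fixtures with known ground truth.

Real specimens for this workflow cannot be re-imaged, so every stage is
exercised on phantoms: a branching vessel tree (the 3D roadmap both
modalities share), rendered once as a fluorescence stack with depth
attenuation and once — after a known similarity-plus-TPS deformation
standing in for fixation/embedding distortion — as an inverted-contrast
microCT block with planar, slightly tilted faces.  The generating transform,
the target position in both frames and the block geometry are recorded as
ground truth for recovery tests.

Default conditions emulate the real acquisitions: microCT at 0.75 µm
isotropic; intravital stacks at (0.5, 0.5, 2) µm (an assumed two-photon
sampling, lateral Nyquist-ish and coarser axially); shrinkage 0.85–0.95 with
rotation ≤ 10° and smooth nonlinear displacement ≤ 3 µm; 15 landmark pairs
at vessel bifurcations with 1 µm localization noise per side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .registration import (
    CompositeTransform,
    LandmarkPairs,
    AffineTransform,
    fit_tps,
)
from .targeting import BlockModel
from .volumes import Plane, Volume, write_volume

__all__ = [
    "VesselTree",
    "PhantomTruth",
    "generate_vessel_tree",
    "render_ivm",
    "sample_deformation",
    "render_microct",
    "make_landmarks",
    "generate_registration_case",
    "generate_pair",
    "DEFAULT_CONFIG",
]

DEFAULT_CONFIG: dict = {
    "extent_um": [100.0, 100.0, 100.0],
    "n_roots": 2,
    "branch_prob": 0.16,
    "radius_root_um": 4.0,
    "radius_decay": 0.8,
    "n_landmarks": 15,
    "landmark_noise_um": 1.0,
    "scale_range": [0.85, 0.95],
    "max_rotation_deg": 10.0,
    "max_nonlinear_um": 3.0,
    "deformation_grid_n": 3,
    "ivm_spacing_um": [0.5, 0.5, 2.0],
    "microct_spacing_um": 0.75,
    "attenuation_tau_um": 80.0,
    "noise_sd": 0.02,
    "block_margin_um": 15.0,
}

_STEP_UM = 5.0
_MIN_RADIUS_UM = 1.5
_MAX_STEPS = 200
_MAX_SEGMENTS = 400


@dataclass
class VesselTree:
    """Branching vessel centerlines: (polyline, radius) segments."""

    segments: list[tuple[np.ndarray, float]]
    bifurcations: np.ndarray
    extent: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("vessel tree has no segments")
        for poly, r in self.segments:
            if len(poly) < 2:
                raise ValueError("polylines need >= 2 points")
            if r <= 0:
                raise ValueError("radii must be > 0")
        self.bifurcations = np.asarray(self.bifurcations, dtype=float).reshape(-1, 3)

    def total_length(self) -> float:
        return float(
            sum(np.linalg.norm(np.diff(poly, axis=0), axis=1).sum() for poly, _ in self.segments)
        )

    def sample_centerline(self, step: float = 1.0):
        """Densely resampled centerline points with per-point radius."""
        pts, radii = [], []
        for poly, r in self.segments:
            seglen = np.linalg.norm(np.diff(poly, axis=0), axis=1)
            cum = np.concatenate([[0.0], np.cumsum(seglen)])
            if cum[-1] == 0:
                continue
            s = np.arange(0.0, cum[-1] + step / 2, step)
            interp = np.column_stack(
                [np.interp(s, cum, poly[:, dim]) for dim in range(3)]
            )
            pts.append(interp)
            radii.append(np.full(len(interp), r))
        return np.concatenate(pts), np.concatenate(radii)


@dataclass
class PhantomTruth:
    """Everything needed to score a recovery attempt against ground truth."""

    deformation: CompositeTransform
    target_ivm: np.ndarray
    target_microct: np.ndarray
    block: BlockModel | None
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.target_ivm = np.asarray(self.target_ivm, dtype=float).reshape(3)
        self.target_microct = np.asarray(self.target_microct, dtype=float).reshape(3)
        mapped = self.deformation.transform_points(self.target_ivm)
        if np.linalg.norm(mapped - self.target_microct) > 1e-6:
            raise ValueError("target_microct inconsistent with the deformation")

    def to_dict(self) -> dict:
        from .registration import transform_to_dict

        return {
            "target_ivm_um": self.target_ivm.tolist(),
            "target_microct_um": self.target_microct.tolist(),
            "deformation": transform_to_dict(self.deformation),
            "block": self.block.to_dict() if self.block else None,
            "seed": self.seed,
            "params": self.params,
        }


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def generate_vessel_tree(
    extent=(100.0, 100.0, 100.0),
    n_roots: int = 2,
    branch_prob: float = 0.16,
    radius_root: float = 4.0,
    radius_decay: float = 0.8,
    seed: int = 0,
) -> VesselTree:
    """Recursive random-walk branching network inside a box.

    Roots start near the shallow face growing inward; segments advance in
    5 µm steps with direction jitter (steered back inward near the walls so
    the network stays inside the imaged tissue), branch with ``branch_prob``
    per step into two children at ``radius × radius_decay``, and terminate
    below a 1.5 µm radius floor — capillary scale, the thinnest tube the
    rendered voxel grids resolve — or at the boundary.  Regenerates (derived
    seeds) until at least one bifurcation exists: the target site sits at a
    bifurcation, as arrested cells do.
    """
    extent = np.asarray(extent, dtype=float)
    if np.any(extent <= 0):
        raise ValueError("extent must be positive")
    for attempt in range(20):
        rng = np.random.default_rng(seed + 7919 * attempt)
        segments: list[tuple[np.ndarray, float]] = []
        bifurcations: list[np.ndarray] = []
        stack = []
        for _ in range(n_roots):
            pos = np.array(
                [rng.uniform(0.2, 0.8) * extent[0],
                 rng.uniform(0.2, 0.8) * extent[1],
                 rng.uniform(0.02, 0.1) * extent[2]]
            )
            direction = _unit(np.array([rng.normal(0, 0.3), rng.normal(0, 0.3), 1.0]))
            stack.append((pos, direction, radius_root))
        while stack and len(segments) < _MAX_SEGMENTS:
            pos, direction, radius = stack.pop()
            if radius < _MIN_RADIUS_UM:
                continue
            poly = [pos.copy()]
            for _ in range(_MAX_STEPS):
                direction = _unit(direction + 0.35 * rng.normal(size=3))
                # steer back inward near the walls: the network stays inside
                # the imaged tissue instead of dying out at the box faces
                margin = 10.0
                near_wall = (pos < margin) | (pos > extent - margin)
                if near_wall.any():
                    direction = _unit(direction + 1.2 * _unit(extent / 2 - pos))
                pos = pos + _STEP_UM * direction
                if np.any(pos < 0) or np.any(pos > extent):
                    pos = np.clip(pos, 0, extent)
                    poly.append(pos.copy())
                    break
                poly.append(pos.copy())
                if rng.random() < branch_prob:
                    bifurcations.append(pos.copy())
                    for _child in range(2):
                        child_dir = _unit(direction + 0.8 * rng.normal(size=3))
                        stack.append((pos.copy(), child_dir, radius * radius_decay))
                    break
            if len(poly) >= 2:
                segments.append((np.array(poly), radius))
        if segments and (branch_prob == 0 or bifurcations):
            return VesselTree(
                segments=segments,
                bifurcations=np.array(bifurcations).reshape(-1, 3),
                extent=tuple(extent),
            )
    raise RuntimeError("could not generate a non-empty vessel tree with a bifurcation")


def _rasterize_tubes(tree: VesselTree, shape, spacing, origin=(0.0, 0.0, 0.0)):
    """Boolean inside-tube grid: voxel center within radius of the centerline."""
    centers, radii = tree.sample_centerline(step=min(1.0, min(spacing)))
    tree_kd = cKDTree(centers)
    nz, ny, nx = shape
    sx, sy, sz = spacing
    ox, oy, oz = origin
    zz, yy, xx = np.meshgrid(
        oz + np.arange(nz) * sz, oy + np.arange(ny) * sy, ox + np.arange(nx) * sx,
        indexing="ij",
    )
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    rmax = radii.max()
    dist, idx = tree_kd.query(pts, distance_upper_bound=rmax + 1e-9, workers=-1)
    inside = np.zeros(len(pts), dtype=bool)
    ok = np.isfinite(dist)
    inside[ok] = dist[ok] <= radii[idx[ok]]
    return inside.reshape(shape)


def render_ivm(
    tree: VesselTree,
    target,
    spacing=(0.5, 0.5, 2.0),
    attenuation_tau: float = 80.0,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[Volume, Volume]:
    """Two-channel fluorescence rendering: vessels and the target cell.

    Tubes are rasterized, blurred (σ = 1 µm), attenuated by exp(−z/τ) along
    the optical axis, and degraded with Gaussian noise.  The cell channel is
    a 10×8×8 µm ellipsoid at the target position.
    """
    rng = np.random.default_rng(seed)
    spacing = tuple(float(s) for s in spacing)
    sx, sy, sz = spacing
    ex, ey, ez = tree.extent
    shape = (int(np.ceil(ez / sz)) + 1, int(np.ceil(ey / sy)) + 1, int(np.ceil(ex / sx)) + 1)
    inside = _rasterize_tubes(tree, shape, spacing)
    img = inside.astype(float)
    img = ndimage.gaussian_filter(img, sigma=(1.0 / sz, 1.0 / sy, 1.0 / sx))
    z_um = np.arange(shape[0]) * sz
    if np.isfinite(attenuation_tau):
        img *= np.exp(-z_um / attenuation_tau)[:, None, None]
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    vessels = Volume(img, spacing, frame="ivm")

    target = np.asarray(target, dtype=float).reshape(3)
    zz, yy, xx = np.meshgrid(
        np.arange(shape[0]) * sz, np.arange(shape[1]) * sy, np.arange(shape[2]) * sx,
        indexing="ij",
    )
    # 10x8x8 µm ellipsoid -> semi-axes (5, 4, 4)
    e = (
        ((xx - target[0]) / 5.0) ** 2
        + ((yy - target[1]) / 4.0) ** 2
        + ((zz - target[2]) / 4.0) ** 2
    )
    cell_img = (e <= 1.0).astype(float)
    cell_img = ndimage.gaussian_filter(cell_img, sigma=(1.0 / sz, 1.0 / sy, 1.0 / sx))
    if noise_sd > 0:
        cell_img = cell_img + rng.normal(0.0, noise_sd, size=cell_img.shape)
    cell = Volume(cell_img, spacing, frame="ivm")
    return vessels, cell


def sample_deformation(
    extent=(100.0, 100.0, 100.0),
    scale_range=(0.85, 0.95),
    max_nonlinear_displacement: float = 3.0,
    grid_n: int = 3,
    seed: int = 0,
    max_rotation_deg: float = 10.0,
) -> CompositeTransform:
    """Random similarity (shrinkage) composed with a smooth TPS perturbation.

    Scale ~ U(scale_range), rotation angle ~ U(0, 10°) about a random axis,
    translation ~ U(−10, 10) µm per axis.  The nonlinear part is a TPS built
    on a ``grid_n³`` control grid whose displacements are random directions
    with magnitude ~ U(0, max), so the mean displacement magnitude is max/2.
    """
    lo, hi = scale_range
    if not 0 < lo <= hi:
        raise ValueError("invalid scale_range")
    rng = np.random.default_rng(seed)
    extent = np.asarray(extent, dtype=float)
    c = rng.uniform(lo, hi)
    axis = _unit(rng.normal(size=3))
    angle = np.deg2rad(rng.uniform(0.0, max_rotation_deg))
    R = Rotation.from_rotvec(angle * axis).as_matrix()
    center = extent / 2
    t = center - c * R @ center + rng.uniform(-10.0, 10.0, size=3)
    similarity = AffineTransform(c * R, t, kind="similarity",
                                 source_frame="ivm", target_frame="microct")

    axes = [np.linspace(0.0, e, grid_n) for e in extent]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    grid_mapped = similarity.transform_points(grid)
    if max_nonlinear_displacement > 0:
        dirs = rng.normal(size=grid_mapped.shape)
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        mags = rng.uniform(0.0, max_nonlinear_displacement, size=len(grid_mapped))
        disp = dirs * mags[:, None]
    else:
        disp = np.zeros_like(grid_mapped)
    tps_pairs = LandmarkPairs(grid_mapped, grid_mapped + disp,
                              source_frame="microct", target_frame="microct")
    tps = fit_tps(tps_pairs, lam=0.0)
    return CompositeTransform([similarity, tps])


def render_microct(
    tree: VesselTree,
    deformation: CompositeTransform,
    spacing: float = 0.75,
    block_margin: float = 15.0,
    noise_sd: float = 0.02,
    seed: int = 0,
    face_tilt_deg: float = 2.0,
) -> tuple[Volume, BlockModel]:
    """Inverted-contrast microCT rendering of the deformed, embedded tree.

    The resin block extends ``block_margin`` µm beyond the deformed tissue;
    the front face (outward ≈ −z) and flank (outward ≈ −x) are planes tilted
    by ``face_tilt_deg`` (≤ 3°).  Intensities: air 0, resin bright, stained
    tissue intermediate, vessels darkest — vessels show up in microCT by
    their *lower* density, the inverse of the fluorescence contrast.
    """
    rng = np.random.default_rng(seed)
    centers, radii = tree.sample_centerline(step=1.0)
    mapped = deformation.transform_points(centers)
    lo = mapped.min(axis=0) - block_margin
    hi = mapped.max(axis=0) + block_margin
    air = 3.0  # µm of air framing the block in the grid
    s = float(spacing)
    shape = tuple(int(np.ceil((hi[ax] - lo[ax] + 2 * air) / s)) + 1 for ax in (2, 1, 0))
    origin = tuple(lo - air)

    tilt = np.deg2rad(face_tilt_deg)
    front = Plane.through(point=np.array([0.0, 0.0, lo[2]]) + [hi[0] / 2, hi[1] / 2, 0.0],
                          normal=np.array([np.sin(tilt), 0.0, -np.cos(tilt)]))
    flank = Plane.through(point=np.array([lo[0], hi[1] / 2, hi[2] / 2]),
                          normal=np.array([-np.cos(tilt), np.sin(tilt), 0.0]))
    others = [
        Plane((hi[0] / 2, hi[1] / 2, hi[2]), (0.0, 0.0, 1.0)),
        Plane((hi[0], hi[1] / 2, hi[2] / 2), (1.0, 0.0, 0.0)),
        Plane((hi[0] / 2, lo[1], hi[2] / 2), (0.0, -1.0, 0.0)),
        Plane((hi[0] / 2, hi[1], hi[2] / 2), (0.0, 1.0, 0.0)),
    ]
    block = BlockModel(front_face=front, flank=flank, other_faces=others)

    nz, ny, nx = shape
    ox, oy, oz = origin
    zz, yy, xx = np.meshgrid(
        oz + np.arange(nz) * s, oy + np.arange(ny) * s, ox + np.arange(nx) * s,
        indexing="ij",
    )
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    inside_block = np.ones(len(pts), dtype=bool)
    for plane in [front, flank] + others:
        inside_block &= plane.signed_distance(pts) <= 0

    tree_kd = cKDTree(mapped)
    rmax = radii.max()
    dist, idx = tree_kd.query(pts, distance_upper_bound=rmax + 12.0, workers=-1)
    ok = np.isfinite(dist)
    vessel = np.zeros(len(pts), dtype=bool)
    vessel[ok] = dist[ok] <= radii[idx[ok]]
    tissue = np.zeros(len(pts), dtype=bool)
    tissue[ok] = dist[ok] <= radii[idx[ok]] + 10.0

    img = np.zeros(len(pts))
    img[inside_block] = 200.0                       # resin
    img[inside_block & tissue] = 120.0              # stained tissue
    img[inside_block & vessel] = 40.0               # vessels (lowest density)
    img = img.reshape(shape)
    img = ndimage.gaussian_filter(img, sigma=1.0 / s)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd * 200.0, size=img.shape)
    vol = Volume(img, (s, s, s), origin=origin, frame="microct")
    return vol, block


def make_landmarks(
    tree: VesselTree,
    deformation: CompositeTransform,
    target_ivm,
    n_landmarks: int = 15,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> LandmarkPairs:
    """Noisy corresponding pairs at vessel bifurcations.

    A uniform random sample of ``n_landmarks`` bifurcations is used
    (corresponding structural features seeded across the shared network);
    polyline vertices supplement them if the tree branches too little.
    Independent N(0, σ) localization noise is added on both sides.
    """
    rng = np.random.default_rng(seed)
    target_ivm = np.asarray(target_ivm, dtype=float).reshape(3)
    candidates = tree.bifurcations
    if len(candidates) < n_landmarks:
        verts = np.concatenate([poly[1:-1] for poly, _ in tree.segments if len(poly) > 2])
        extra = verts[rng.choice(len(verts), size=min(len(verts), 3 * n_landmarks),
                                 replace=False)]
        candidates = np.concatenate([candidates, extra])
    chosen = candidates[rng.choice(len(candidates), size=n_landmarks, replace=False)]
    mapped = deformation.transform_points(chosen)
    src = chosen + rng.normal(0.0, noise_sd, size=chosen.shape)
    dst = mapped + rng.normal(0.0, noise_sd, size=mapped.shape)
    return LandmarkPairs(src, dst, labels=[f"bif{i}" for i in range(len(src))])


def generate_registration_case(
    seed: int, config: dict | None = None
) -> tuple[LandmarkPairs, PhantomTruth]:
    """Landmarks + ground truth for one phantom, without volume rendering.

    This is the fixture the registration-accuracy Monte-Carlo runs on: the
    vessel tree, the ground-truth deformation, the bifurcation landmarks with
    localization noise, and the target (adjacent to a bifurcation) in both
    frames.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    rng = np.random.default_rng(seed)
    tree = generate_vessel_tree(
        extent=cfg["extent_um"],
        n_roots=cfg["n_roots"],
        branch_prob=cfg["branch_prob"],
        radius_root=cfg["radius_root_um"],
        radius_decay=cfg["radius_decay"],
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    deformation = sample_deformation(
        extent=cfg["extent_um"],
        scale_range=tuple(cfg["scale_range"]),
        max_nonlinear_displacement=cfg["max_nonlinear_um"],
        grid_n=cfg["deformation_grid_n"],
        seed=int(rng.integers(0, 2**31 - 1)),
        max_rotation_deg=cfg["max_rotation_deg"],
    )
    bif = tree.bifurcations[int(rng.integers(0, len(tree.bifurcations)))]
    target_ivm = bif + rng.uniform(-3.0, 3.0, size=3)  # cell sits at the bifurcation
    target_microct = deformation.transform_points(target_ivm)
    pairs = make_landmarks(
        tree, deformation, target_ivm,
        n_landmarks=cfg["n_landmarks"],
        noise_sd=cfg["landmark_noise_um"],
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    truth = PhantomTruth(
        deformation=deformation,
        target_ivm=target_ivm,
        target_microct=target_microct,
        block=None,
        seed=seed,
        params=cfg,
    )
    return pairs, truth


def generate_pair(config: dict | None, seed: int, out_dir=None):
    """Full fixture: IVM channels, microCT block, landmarks, truth.

    If ``out_dir`` is given, writes ivm_vessels.tif, ivm_cell.tif,
    microct.nrrd, landmarks.csv, truth.json and config.yaml there —
    byte-reproducible per seed.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    pairs, truth = generate_registration_case(seed, cfg)
    rng = np.random.default_rng(seed + 10_007)
    # rebuild the tree from the same derived seed the case used
    case_rng = np.random.default_rng(seed)
    tree = generate_vessel_tree(
        extent=cfg["extent_um"],
        n_roots=cfg["n_roots"],
        branch_prob=cfg["branch_prob"],
        radius_root=cfg["radius_root_um"],
        radius_decay=cfg["radius_decay"],
        seed=int(case_rng.integers(0, 2**31 - 1)),
    )
    vessels, cell = render_ivm(
        tree, truth.target_ivm,
        spacing=cfg["ivm_spacing_um"],
        attenuation_tau=cfg["attenuation_tau_um"],
        noise_sd=cfg["noise_sd"],
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    microct, block = render_microct(
        tree, truth.deformation,
        spacing=cfg["microct_spacing_um"],
        block_margin=cfg["block_margin_um"],
        noise_sd=cfg["noise_sd"],
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    truth = PhantomTruth(
        deformation=truth.deformation,
        target_ivm=truth.target_ivm,
        target_microct=truth.target_microct,
        block=block,
        seed=seed,
        params=cfg,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_volume(vessels, out / "ivm_vessels.tif")
        write_volume(cell, out / "ivm_cell.tif")
        write_volume(microct, out / "microct.nrrd")
        pairs.to_csv(out / "landmarks.csv")
        (out / "truth.json").write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True))
        (out / "config.yaml").write_text(yaml.safe_dump(cfg))
    return {
        "ivm_vessels": vessels,
        "ivm_cell": cell,
        "microct": microct,
        "block": block,
        "landmarks": pairs,
        "truth": truth,
        "tree": tree,
    }
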