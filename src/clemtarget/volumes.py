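"""Volume data model, file I/O, depth normalization, resampling, oblique slicing.

Conventions used throughout the package:

* Voxel arrays are stored depth-slowest, i.e. ``voxels[k, j, i]`` where the
  TIFF stack page index ``k`` runs along the acquisition/penetration axis
  (optical z for intravital stacks, scan z for microCT).
* Spacing is given as ``(sx, sy, sz)`` in µm per voxel, so the physical
  coordinate of voxel index ``(i, j, k)`` is ``origin + (i*sx, j*sy, k*sz)``
  (voxel-center convention, 0-based indices).
* All geometry downstream (registration, targeting, trimming) operates on
  physical µm coordinates, never on voxel indices — the two modalities have
  different, partly anisotropic spacings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml
from scipy import ndimage

__all__ = [
    "Volume",
    "SectionImage",
    "Plane",
    "read_volume",
    "write_volume",
    "read_section",
    "write_section",
    "normalize_depth_intensity",
    "resample",
    "extract_oblique_slice",
]

FRAMES = ("ivm", "microct")


@dataclass
class Volume:
    """A 3D scalar grid with physical spacing, origin and a frame tag.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Scalar grid, stack-page-slowest.
    spacing : tuple of float
        ``(sx, sy, sz)`` µm per voxel.
    origin : tuple of float
        Physical coordinate (µm) of voxel (0, 0, 0)'s center.
    frame : str
        ``"ivm"`` or ``"microct"``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    frame: str = "ivm"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("voxels must be a 3D grid with >=1 voxel per axis")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if self.frame not in FRAMES:
            raise ValueError(f"frame must be one of {FRAMES}, got {self.frame!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size (µm) spanned by voxel centers, per (x, y, z) axis."""
        nz, ny, nx = self.voxels.shape
        sx, sy, sz = self.spacing
        return ((nx - 1) * sx, (ny - 1) * sy, (nz - 1) * sz)

    def index_to_physical(self, kji: np.ndarray) -> np.ndarray:
        """Map (k, j, i) array indices to physical (x, y, z) µm coordinates."""
        kji = np.atleast_2d(np.asarray(kji, dtype=float))
        sx, sy, sz = self.spacing
        ox, oy, oz = self.origin
        xyz = np.column_stack(
            [ox + kji[:, 2] * sx, oy + kji[:, 1] * sy, oz + kji[:, 0] * sz]
        )
        return xyz

    def physical_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Map physical (x, y, z) µm to continuous (k, j, i) array indices."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        sx, sy, sz = self.spacing
        ox, oy, oz = self.origin
        return np.column_stack(
            [(xyz[:, 2] - oz) / sz, (xyz[:, 1] - oy) / sy, (xyz[:, 0] - ox) / sx]
        )


@dataclass
class SectionImage:
    """A 2D physical section (ultramicrotome thick section or virtual slice)."""

    pixels: np.ndarray
    pixel_spacing: float
    label: str = ""
    nominal_depth: float | None = None
    n_outside: int = 0  # samples that fell outside the source volume

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel values must be finite")
        self.pixel_spacing = float(self.pixel_spacing)
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be > 0")


@dataclass
class Plane:
    """An oriented plane: a point on it plus the outward unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        self.normal = np.asarray(self.normal, dtype=float).reshape(3)
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-9:
            raise ValueError("plane normal must be unit length (within 1e-9)")

    @classmethod
    def through(cls, point, normal) -> "Plane":
        """Construct a plane, normalizing the given direction."""
        normal = np.asarray(normal, dtype=float).reshape(3)
        nrm = np.linalg.norm(normal)
        if nrm == 0:
            raise ValueError("zero normal")
        return cls(point, normal / nrm)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance(s), positive on the outward (normal) side."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = (pts - self.point) @ self.normal
        return d if np.asarray(points).ndim == 2 else float(d[0])

    def to_dict(self) -> dict:
        return {"point_um": self.point.tolist(), "normal": self.normal.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Plane":
        return cls.through(d["point_um"], d["normal"])


# ---------------------------------------------------------------------------
# File I/O: TIFF stacks with a YAML sidecar, NRRD via SimpleITK
# ---------------------------------------------------------------------------

_TIFF_SUFFIXES = (".tif", ".tiff")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def read_volume(path, spacing_override=None, frame: str = "ivm") -> Volume:
    """Read a TIFF stack or NRRD file into a :class:`Volume`.

    TIFF carries no spacing, so either ``spacing_override`` or a YAML sidecar
    ``<stem>.yaml`` with ``spacing_um: [sx, sy, sz]`` must be present. NRRD
    spacing (and origin) come from the header; ``spacing_override`` wins if
    given. Integer voxel data round-trips bit-exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    origin = (0.0, 0.0, 0.0)
    if suffix in _TIFF_SUFFIXES:
        voxels = tifffile.imread(path)
        if voxels.ndim == 2:
            voxels = voxels[None]
        spacing = spacing_override
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = yaml.safe_load(sidecar.read_text())
            if spacing is None:
                spacing = meta.get("spacing_um")
            origin = tuple(meta.get("origin_um", origin))
            frame = meta.get("frame", frame)
        if spacing is None:
            raise ValueError(
                f"TIFF volume {path} needs spacing_override or a YAML sidecar"
            )
    elif suffix == ".nrrd":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        voxels = sitk.GetArrayFromImage(img)  # (z, y, x)
        spacing = spacing_override if spacing_override is not None else img.GetSpacing()
        origin = tuple(img.GetOrigin())
    else:
        raise ValueError(f"unsupported volume format: {suffix}")
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive spacing {spacing}")
    return Volume(voxels, spacing, origin=origin, frame=frame)


def write_volume(volume: Volume, path) -> Path:
    """Write a :class:`Volume`; format chosen by extension (.tif/.tiff/.nrrd)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in _TIFF_SUFFIXES:
        tifffile.imwrite(path, volume.voxels, photometric="minisblack")
        _sidecar_path(path).write_text(
            yaml.safe_dump(
                {
                    "spacing_um": list(volume.spacing),
                    "origin_um": list(volume.origin),
                    "frame": volume.frame,
                }
            )
        )
    elif suffix == ".nrrd":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(volume.voxels)
        img.SetSpacing(volume.spacing)
        img.SetOrigin(volume.origin)
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported volume format: {suffix}")
    return path


def write_section(section: SectionImage, path) -> Path:
    path = Path(path)
    if path.suffix.lower() not in _TIFF_SUFFIXES:
        raise ValueError("sections are written as single-page TIFF")
    tifffile.imwrite(path, section.pixels)
    _sidecar_path(path).write_text(
        yaml.safe_dump(
            {
                "pixel_spacing_um": section.pixel_spacing,
                "label": section.label,
                "nominal_depth_um": section.nominal_depth,
            }
        )
    )
    return path


def read_section(path, pixel_spacing=None) -> SectionImage:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pixels = tifffile.imread(path)
    label, nominal_depth = "", None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text())
        pixel_spacing = pixel_spacing or meta.get("pixel_spacing_um")
        label = meta.get("label", "")
        nominal_depth = meta.get("nominal_depth_um")
    if pixel_spacing is None:
        raise ValueError(f"section {path} needs pixel_spacing or a YAML sidecar")
    return SectionImage(pixels, float(pixel_spacing), label=label, nominal_depth=nominal_depth)


# ---------------------------------------------------------------------------
# Depth-gradient intensity normalization
# ---------------------------------------------------------------------------


def normalize_depth_intensity(volume: Volume, foreground_quantile: float = 0.75) -> Volume:
    """Equalize per-depth-slice foreground statistics.

    Both modalities show a depth intensity gradient: two-photon excitation
    attenuates with imaging depth, and heavy-metal stain penetrates the biopsy
    incompletely.  For each slice along the depth axis, voxels strictly above
    the slice's ``foreground_quantile`` define foreground; the slice is then
    linearly rescaled so that its foreground mean and SD match the global
    foreground mean and SD.  Because the foreground set is quantile-defined it
    is invariant under the per-slice affine map, which makes the operation
    idempotent.

    Slices with an empty foreground (e.g. perfectly constant slices) are
    returned unchanged and reported through a ``UserWarning``.
    """
    if volume.voxels.shape[0] < 2:
        raise ValueError("need >=2 slices along the depth axis")
    data = volume.voxels.astype(float)
    masks: list[np.ndarray | None] = []
    fg_values = []
    for sl in data:
        thr = np.quantile(sl, foreground_quantile)
        m = sl > thr
        if not m.any():
            masks.append(None)
        else:
            masks.append(m)
            fg_values.append(sl[m])
    empty = [k for k, m in enumerate(masks) if m is None]
    if empty:
        warnings.warn(
            f"slices {empty} have empty foreground at quantile "
            f"{foreground_quantile}; left unchanged",
            UserWarning,
            stacklevel=2,
        )
    if not fg_values:
        return Volume(data, volume.spacing, volume.origin, volume.frame)
    allfg = np.concatenate([v.ravel() for v in fg_values])
    gmean, gsd = float(allfg.mean()), float(allfg.std())
    out = np.empty_like(data)
    for k, (sl, m) in enumerate(zip(data, masks)):
        if m is None:
            out[k] = sl
            continue
        mu, sd = float(sl[m].mean()), float(sl[m].std())
        if sd > 0 and gsd > 0:
            out[k] = (sl - mu) * (gsd / sd) + gmean
        else:
            out[k] = sl - mu + gmean
    return Volume(out, volume.spacing, volume.origin, volume.frame)


# ---------------------------------------------------------------------------
# Resampling and oblique virtual sections
# ---------------------------------------------------------------------------


def resample(volume: Volume, new_spacing) -> Volume:
    """Trilinear resampling onto a grid with the requested spacing.

    The new grid shares the volume origin; the number of voxels per axis is
    chosen so the physical extent is preserved to within one voxel.
    Resampling to the original spacing is the identity.
    """
    new_spacing = tuple(float(s) for s in np.broadcast_to(new_spacing, (3,)))
    if any(s <= 0 for s in new_spacing):
        raise ValueError("new_spacing must be positive")
    old = volume.spacing
    nz, ny, nx = volume.voxels.shape
    # array axes (z, y, x) pair with spacing components (sz, sy, sx)
    old_axes = (old[2], old[1], old[0])
    new_axes = (new_spacing[2], new_spacing[1], new_spacing[0])
    new_shape = tuple(
        max(1, int(round((n - 1) * so / sn)) + 1)
        for n, so, sn in zip((nz, ny, nx), old_axes, new_axes)
    )
    coords = np.meshgrid(
        *[np.arange(n_new) * sn / so for n_new, sn, so in zip(new_shape, new_axes, old_axes)],
        indexing="ij",
    )
    vals = ndimage.map_coordinates(
        volume.voxels.astype(float), coords, order=1, mode="nearest"
    )
    return Volume(vals, new_spacing, origin=volume.origin, frame=volume.frame)


def extract_oblique_slice(
    volume: Volume,
    plane: Plane,
    u_axis,
    extent: tuple[float, float],
    pixel_spacing: float,
    fill: float = 0.0,
) -> SectionImage:
    """Sample a virtual planar section through the volume.

    The slice rectangle of physical size ``extent = (w, h)`` µm is centered on
    ``plane.point``; in-plane axes are ``u = u_axis`` (slice columns) and
    ``v = normal × u`` (slice rows).  Pixel ``(b, a)`` samples the volume by
    trilinear interpolation at

        ``plane.point + ((a + 0.5)·ps − w/2)·u + ((b + 0.5)·ps − h/2)·v``

    (pixel-center convention).  Samples falling outside the volume take the
    fill value and are counted in ``SectionImage.n_outside`` — the trimmed
    block faces sit at the volume boundary, so this is routine, not an error.
    """
    u = np.asarray(u_axis, dtype=float).reshape(3)
    if abs(np.linalg.norm(u) - 1.0) > 1e-6:
        raise ValueError("u_axis must be a unit vector")
    if abs(float(u @ plane.normal)) > 1e-6:
        raise ValueError("u_axis must be orthogonal to the plane normal")
    v = np.cross(plane.normal, u)
    w, h = float(extent[0]), float(extent[1])
    ps = float(pixel_spacing)
    if ps <= 0 or w <= 0 or h <= 0:
        raise ValueError("extent and pixel_spacing must be positive")
    nu = max(1, int(round(w / ps)))
    nv = max(1, int(round(h / ps)))
    a_off = (np.arange(nu) + 0.5) * ps - w / 2.0
    b_off = (np.arange(nv) + 0.5) * ps - h / 2.0
    pts = (
        plane.point[None, None, :]
        + a_off[None, :, None] * u[None, None, :]
        + b_off[:, None, None] * v[None, None, :]
    )  # (nv, nu, 3)
    idx = volume.physical_to_index(pts.reshape(-1, 3))  # (n, 3) as (k, j, i)
    nzyx = volume.voxels.shape
    outside = np.zeros(idx.shape[0], dtype=bool)
    for ax in range(3):
        outside |= (idx[:, ax] < 0) | (idx[:, ax] > nzyx[ax] - 1)
    vals = ndimage.map_coordinates(
        volume.voxels.astype(float), idx.T, order=1, mode="constant", cval=fill
    )
    vals[outside] = fill
    return SectionImage(
        vals.reshape(nv, nu), ps, n_outside=int(outside.sum())
    )
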