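"""Landmark-based 3D transforms: rigid/similarity/affine/TPS, with diagnostics.

Fixation and resin embedding shrink and distort the tissue, so registering an
intravital volume onto the microCT scan of the embedded block needs at least
an isotropic scale and, for micrometer accuracy, a smooth nonlinear warp.
This module fits the full ladder

    rigid  ⊂  similarity  ⊂  affine  ⊂  thin-plate spline (TPS)

to paired landmarks (physical µm), applies and inverts the resulting maps,
and reports two error figures:

* FRE — fiducial registration error, the RMS residual at the landmarks;
* LOO-TRE — leave-one-out target registration error, an unbiased surrogate
  for the error at a point that was *not* used in the fit.

Rigid and similarity fits use the closed-form Procrustes/Umeyama solution
(SVD with proper-rotation sign correction).  The TPS uses the 3D biharmonic
kernel φ(r) = r — the correct Green's function in three dimensions — solving
the standard bordered linear system; the regularization λ is added to the
kernel diagonal, so λ=0 interpolates the landmarks exactly and λ→∞ tends to
the affine least-squares fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .segmentation import PointSet

__all__ = [
    "LandmarkPairs",
    "AffineTransform",
    "TPSTransform",
    "CompositeTransform",
    "NumericalInverseTransform",
    "RegistrationReport",
    "DegenerateConfigurationError",
    "FrameMismatchError",
    "fit_rigid",
    "fit_similarity",
    "fit_affine",
    "fit_tps",
    "apply",
    "invert",
    "fre",
    "loo_tre",
    "register_two_stage",
    "transform_to_dict",
    "transform_from_dict",
    "save_transform",
    "load_transform",
]

MODEL_MIN_POINTS = {"rigid": 3, "similarity": 3, "affine": 4, "tps": 5}
_COND_LIMIT = 1e8


class DegenerateConfigurationError(ValueError):
    """Landmark configuration insufficient for the requested model."""


class FrameMismatchError(ValueError):
    """Points offered in a frame the transform does not start from."""


@dataclass
class LandmarkPairs:
    """N corresponding points in two frames — the registration's sole input."""

    source: np.ndarray
    target: np.ndarray
    labels: list[str] | None = None
    source_frame: str = "ivm"
    target_frame: str = "microct"

    def __post_init__(self) -> None:
        self.source = np.asarray(self.source, dtype=float).reshape(-1, 3)
        self.target = np.asarray(self.target, dtype=float).reshape(-1, 3)
        if len(self.source) != len(self.target):
            raise ValueError("source/target must pair up")
        if len(self.source) < 1:
            raise ValueError("need at least one pair")
        if not (np.all(np.isfinite(self.source)) and np.all(np.isfinite(self.target))):
            raise ValueError("landmarks must be finite")
        if self.labels is not None and len(self.labels) != len(self.source):
            raise ValueError("labels length mismatch")

    def __len__(self) -> int:
        return len(self.source)

    def drop(self, i: int) -> "LandmarkPairs":
        keep = np.arange(len(self)) != i
        labels = [l for k, l in enumerate(self.labels) if keep[k]] if self.labels else None
        return LandmarkPairs(
            self.source[keep], self.target[keep], labels,
            self.source_frame, self.target_frame,
        )

    @classmethod
    def from_csv(cls, path, source_frame="ivm", target_frame="microct") -> "LandmarkPairs":
        df = pd.read_csv(path)
        cols = ["src_x_um", "src_y_um", "src_z_um", "dst_x_um", "dst_y_um", "dst_z_um"]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"landmark CSV missing columns {missing}")
        labels = df["label"].astype(str).tolist() if "label" in df.columns else None
        return cls(df[cols[:3]].to_numpy(), df[cols[3:]].to_numpy(), labels,
                   source_frame, target_frame)

    def to_csv(self, path) -> Path:
        labels = self.labels or [f"p{i}" for i in range(len(self))]
        df = pd.DataFrame(
            {
                "label": labels,
                "src_x_um": self.source[:, 0],
                "src_y_um": self.source[:, 1],
                "src_z_um": self.source[:, 2],
                "dst_x_um": self.target[:, 0],
                "dst_y_um": self.target[:, 1],
                "dst_z_um": self.target[:, 2],
            }
        )
        df.to_csv(path, index=False)
        return Path(path)


@dataclass
class AffineTransform:
    """x ↦ matrix · x + translation, with kind ∈ {rigid, similarity, affine}."""

    matrix: np.ndarray
    translation: np.ndarray
    kind: str = "affine"
    source_frame: str | None = None
    target_frame: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.kind not in ("rigid", "similarity", "affine"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "rigid":
            if (
                np.abs(self.matrix.T @ self.matrix - np.eye(3)).max() > 1e-8
                or abs(np.linalg.det(self.matrix) - 1.0) > 1e-8
            ):
                raise ValueError("rigid matrix must be proper-orthogonal")
        elif self.kind == "similarity":
            c = np.linalg.det(self.matrix) ** (1.0 / 3.0)
            if not np.isreal(c) or c <= 0:
                raise ValueError("similarity must have positive scale")
            R = self.matrix / c
            if np.abs(R.T @ R - np.eye(3)).max() > 1e-8:
                raise ValueError("similarity matrix must be scale x rotation")

    @property
    def scale(self) -> float:
        """Isotropic scale factor (cube root of the determinant)."""
        return float(np.linalg.det(self.matrix) ** (1.0 / 3.0))

    def transform_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix.T + self.translation
        return out if np.asarray(points).ndim == 2 else out[0]


@dataclass
class TPSTransform:
    """3D thin-plate spline: affine part plus φ(r)=r kernel on control points.

    Side conditions Σ w_i = 0 and Σ w_i p_iᵀ = 0 hold by construction of the
    bordered system and are validated here, guaranteeing the kernel part
    decays to the affine behavior far from the controls.
    """

    control_points: np.ndarray
    kernel_weights: np.ndarray
    affine_part: AffineTransform
    lam: float = 0.0
    source_frame: str | None = None
    target_frame: str | None = None

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, dtype=float).reshape(-1, 3)
        self.kernel_weights = np.asarray(self.kernel_weights, dtype=float).reshape(-1, 3)
        if len(self.control_points) != len(self.kernel_weights):
            raise ValueError("control_points/kernel_weights length mismatch")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        scale = max(1.0, np.abs(self.kernel_weights).max(initial=0.0))
        if np.abs(self.kernel_weights.sum(axis=0)).max() > 1e-6 * scale:
            raise ValueError("TPS side condition sum(w) = 0 violated")
        pscale = max(1.0, np.abs(self.control_points).max(initial=0.0))
        if np.abs(self.kernel_weights.T @ self.control_points).max() > 1e-6 * scale * pscale:
            raise ValueError("TPS side condition sum(w p^T) = 0 violated")

    def transform_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        K = cdist(pts, self.control_points)  # φ(r) = r
        out = self.affine_part.transform_points(pts) + K @ self.kernel_weights
        return out if np.asarray(points).ndim == 2 else out[0]


@dataclass
class CompositeTransform:
    """Ordered transforms applied left-to-right (first entry first)."""

    transforms: list

    def __post_init__(self) -> None:
        if not self.transforms:
            raise ValueError("composite needs at least one transform")

    @property
    def source_frame(self):
        return self.transforms[0].source_frame

    @property
    def target_frame(self):
        return self.transforms[-1].target_frame

    def transform_points(self, points: np.ndarray) -> np.ndarray:
        out = points
        for t in self.transforms:
            out = t.transform_points(out)
        return out


class ConvergenceError(RuntimeError):
    pass


@dataclass
class NumericalInverseTransform:
    """Fixed-point inverse of a smooth forward map (used for TPS).

    Solves T(x) = y per point by iterating x ← x − (T(x) − y) from an
    affine-inverse initial guess; valid for the small nonlinear deformations
    this pipeline deals in (embedding distortion of a few µm).
    """

    forward: object
    tol: float = 1e-4
    max_iter: int = 100
    source_frame: str | None = None
    target_frame: str | None = None

    def _affine_start(self):
        fwd = self.forward
        if isinstance(fwd, TPSTransform):
            return _invert_affine(fwd.affine_part)
        return None

    def transform_points(self, points: np.ndarray) -> np.ndarray:
        y = np.atleast_2d(np.asarray(points, dtype=float))
        start = self._affine_start()
        x = start.transform_points(y) if start is not None else y.copy()
        for _ in range(self.max_iter):
            resid = self.forward.transform_points(x) - y
            err = np.linalg.norm(resid, axis=1).max()
            if err < self.tol:
                break
            x = x - resid
        else:
            raise ConvergenceError(
                f"numerical inverse did not converge (residual {err:.3g} µm)"
            )
        return x if np.asarray(points).ndim == 2 else x[0]


@dataclass
class RegistrationReport:
    """Fit diagnostics attached to a registration result."""

    n_landmarks: int
    fre_rms: float
    loo_tre_rms: float
    transform: object = None

    def __post_init__(self) -> None:
        if self.fre_rms < 0 or self.loo_tre_rms < 0:
            raise ValueError("error metrics must be >= 0")

    def to_dict(self) -> dict:
        return {
            "n_landmarks": self.n_landmarks,
            "fre_rms_um": self.fre_rms,
            "loo_tre_rms_um": self.loo_tre_rms,
        }


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _check_configuration(src: np.ndarray, model: str) -> None:
    n_min = MODEL_MIN_POINTS[model]
    if len(src) < n_min:
        raise DegenerateConfigurationError(
            f"{model} fit needs >= {n_min} pairs, got {len(src)}"
        )
    centered = src - src.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    rank_needed = 2 if model in ("rigid", "similarity") else 3
    tol = max(src.shape) * np.finfo(float).eps * (sv[0] if sv[0] > 0 else 1.0)
    rank = int((sv > tol).sum())
    if rank < rank_needed:
        kind = "collinear" if rank_needed == 2 else "coplanar"
        raise DegenerateConfigurationError(f"source landmarks are {kind}")
    if sv[rank_needed - 1] > 0 and sv[0] / sv[rank_needed - 1] > _COND_LIMIT:
        raise DegenerateConfigurationError("landmark configuration is ill-conditioned")


def _umeyama(src: np.ndarray, dst: np.ndarray, with_scale: bool):
    n = len(src)
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    S, D = src - mu_s, dst - mu_d
    cov = D.T @ S / n
    U, s, Vt = np.linalg.svd(cov)
    sign = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
    d = np.array([1.0, 1.0, sign if sign != 0 else 1.0])
    R = U @ np.diag(d) @ Vt
    if with_scale:
        var_s = (S**2).sum() / n
        if var_s == 0:
            raise DegenerateConfigurationError("zero source variance")
        c = float((s * d).sum() / var_s)
        if c <= 0:
            raise DegenerateConfigurationError("non-positive similarity scale")
    else:
        c = 1.0
    t = mu_d - c * (R @ mu_s)
    return c, R, t


def fit_rigid(pairs: LandmarkPairs) -> AffineTransform:
    """Least-squares rigid transform (Procrustes, proper rotation enforced)."""
    _check_configuration(pairs.source, "rigid")
    _, R, t = _umeyama(pairs.source, pairs.target, with_scale=False)
    return AffineTransform(R, t, kind="rigid",
                           source_frame=pairs.source_frame,
                           target_frame=pairs.target_frame)


def fit_similarity(pairs: LandmarkPairs) -> AffineTransform:
    """Least-squares similarity (isotropic scale · rotation + translation)."""
    _check_configuration(pairs.source, "similarity")
    c, R, t = _umeyama(pairs.source, pairs.target, with_scale=True)
    return AffineTransform(c * R, t, kind="similarity",
                           source_frame=pairs.source_frame,
                           target_frame=pairs.target_frame)


def fit_affine(pairs: LandmarkPairs) -> AffineTransform:
    """Least-squares general affine (12 parameters) via the pseudoinverse."""
    _check_configuration(pairs.source, "affine")
    n = len(pairs)
    X = np.column_stack([pairs.source, np.ones(n)])
    sol, _, rank, _ = np.linalg.lstsq(X, pairs.target, rcond=None)
    if rank < 4:
        raise DegenerateConfigurationError("affine design matrix is rank-deficient")
    return AffineTransform(sol[:3].T, sol[3], kind="affine",
                           source_frame=pairs.source_frame,
                           target_frame=pairs.target_frame)


def fit_tps(pairs: LandmarkPairs, lam: float = 0.0) -> TPSTransform:
    """3D thin-plate spline with kernel φ(r)=r and ridge λ on the diagonal."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    _check_configuration(pairs.source, "tps")
    p, y = pairs.source, pairs.target
    n = len(p)
    K = cdist(p, p)
    if lam == 0 and np.any(K[~np.eye(n, dtype=bool)] == 0):
        raise DegenerateConfigurationError("duplicate control points")
    P = np.column_stack([np.ones(n), p])
    A = np.zeros((n + 4, n + 4))
    A[:n, :n] = K + lam * np.eye(n)
    A[:n, n:] = P
    A[n:, :n] = P.T
    b = np.zeros((n + 4, 3))
    b[:n] = y
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as e:
        raise DegenerateConfigurationError(f"singular TPS system: {e}") from e
    W, Aaff = sol[:n], sol[n:]
    affine = AffineTransform(Aaff[1:].T, Aaff[0], kind="affine",
                             source_frame=pairs.source_frame,
                             target_frame=pairs.target_frame)
    return TPSTransform(p, W, affine, lam=lam,
                        source_frame=pairs.source_frame,
                        target_frame=pairs.target_frame)


_FITTERS = {
    "rigid": lambda pairs, **kw: fit_rigid(pairs),
    "similarity": lambda pairs, **kw: fit_similarity(pairs),
    "affine": lambda pairs, **kw: fit_affine(pairs),
    "tps": lambda pairs, **kw: fit_tps(pairs, lam=kw.get("tps_lambda", 0.0)),
}


def fit_model(model: str, pairs: LandmarkPairs, **kw):
    if model not in _FITTERS:
        raise ValueError(f"unknown model {model!r}")
    return _FITTERS[model](pairs, **kw)


# ---------------------------------------------------------------------------
# Application, inversion, diagnostics
# ---------------------------------------------------------------------------


def apply(transform, points: PointSet) -> PointSet:
    """Map a PointSet through a transform, updating its frame tag."""
    src = getattr(transform, "source_frame", None)
    if src is not None and points.frame is not None and points.frame != src:
        raise FrameMismatchError(
            f"points are in frame {points.frame!r}, transform expects {src!r}"
        )
    mapped = transform.transform_points(points.points)
    frame = getattr(transform, "target_frame", None) or points.frame
    return PointSet(mapped, frame=frame, weight=points.weight)


def _invert_affine(t: AffineTransform) -> AffineTransform:
    M = np.linalg.inv(t.matrix)
    return AffineTransform(M, -M @ t.translation, kind=t.kind,
                           source_frame=t.target_frame, target_frame=t.source_frame)


def invert(transform):
    """Analytic inverse for affine maps; fixed-point numeric inverse for TPS."""
    if isinstance(transform, AffineTransform):
        return _invert_affine(transform)
    if isinstance(transform, CompositeTransform):
        return CompositeTransform([invert(t) for t in reversed(transform.transforms)])
    if isinstance(transform, NumericalInverseTransform):
        return transform.forward
    return NumericalInverseTransform(
        transform,
        source_frame=getattr(transform, "target_frame", None),
        target_frame=getattr(transform, "source_frame", None),
    )


def fre(transform, pairs: LandmarkPairs) -> float:
    """Fiducial registration error: RMS of ‖T(x_i) − y_i‖ over the pairs."""
    resid = transform.transform_points(pairs.source) - pairs.target
    return float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))


def loo_tre(model: str, pairs: LandmarkPairs, **fit_kwargs) -> float:
    """Leave-one-out target registration error (RMS over held-out pairs)."""
    n_min = MODEL_MIN_POINTS[model]
    if len(pairs) < n_min + 1:
        raise DegenerateConfigurationError(
            f"LOO-TRE for {model} needs >= {n_min + 1} pairs"
        )
    errs = []
    for i in range(len(pairs)):
        t = fit_model(model, pairs.drop(i), **fit_kwargs)
        pred = t.transform_points(pairs.source[i])
        errs.append(np.sum((pred - pairs.target[i]) ** 2))
    return float(np.sqrt(np.mean(errs)))


def register_two_stage(
    coarse_pairs: LandmarkPairs,
    fine_pairs: LandmarkPairs,
    coarse_model: str = "similarity",
    fine_model: str = "tps",
    tps_lambda: float = 0.01,
) -> tuple[CompositeTransform, RegistrationReport]:
    """Coarse fit, then a fine fit on the residual correspondence.

    The coarse model is fit on ``coarse_pairs``; the fine source points are
    mapped through it and the fine model is fit from the mapped points to the
    fine targets.  Mirrors a coarse overview registration refined with
    higher-magnification acquisitions around the ROI.  The report (FRE and
    leave-one-out TRE of the full composite) is computed on ``fine_pairs``;
    when both stages share the same pairs, each LOO refit drops the held-out
    pair from both stages.
    """

    def _fit_composite(cp: LandmarkPairs, fp: LandmarkPairs) -> CompositeTransform:
        coarse = fit_model(coarse_model, cp, tps_lambda=tps_lambda)
        residual = LandmarkPairs(
            coarse.transform_points(fp.source), fp.target,
            source_frame=cp.target_frame, target_frame=fp.target_frame,
        )
        fine = fit_model(fine_model, residual, tps_lambda=tps_lambda)
        composite = CompositeTransform([coarse, fine])
        return composite

    composite = _fit_composite(coarse_pairs, fine_pairs)
    shared = len(coarse_pairs) == len(fine_pairs) and np.array_equal(
        coarse_pairs.source, fine_pairs.source
    )
    errs = []
    n_min = MODEL_MIN_POINTS[fine_model]
    if len(fine_pairs) >= n_min + 1:
        for i in range(len(fine_pairs)):
            cp = coarse_pairs.drop(i) if shared else coarse_pairs
            t = _fit_composite(cp, fine_pairs.drop(i))
            pred = t.transform_points(fine_pairs.source[i])
            errs.append(np.sum((pred - fine_pairs.target[i]) ** 2))
        loo = float(np.sqrt(np.mean(errs)))
    else:
        loo = 0.0
    report = RegistrationReport(
        n_landmarks=len(fine_pairs),
        fre_rms=fre(composite, fine_pairs),
        loo_tre_rms=loo,
        transform=composite,
    )
    return composite, report


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def transform_to_dict(t) -> dict:
    if isinstance(t, AffineTransform):
        return {
            "type": "affine",
            "kind": t.kind,
            "matrix": t.matrix.tolist(),
            "translation": t.translation.tolist(),
            "source_frame": t.source_frame,
            "target_frame": t.target_frame,
        }
    if isinstance(t, TPSTransform):
        return {
            "type": "tps",
            "control_points": t.control_points.tolist(),
            "weights": t.kernel_weights.tolist(),
            "affine": transform_to_dict(t.affine_part),
            "lambda": t.lam,
            "source_frame": t.source_frame,
            "target_frame": t.target_frame,
        }
    if isinstance(t, CompositeTransform):
        return {"type": "composite", "transforms": [transform_to_dict(x) for x in t.transforms]}
    raise TypeError(f"cannot serialize {type(t).__name__}")


def transform_from_dict(d: dict):
    kind = d["type"]
    if kind == "affine":
        return AffineTransform(
            np.array(d["matrix"]), np.array(d["translation"]), kind=d["kind"],
            source_frame=d.get("source_frame"), target_frame=d.get("target_frame"),
        )
    if kind == "tps":
        return TPSTransform(
            np.array(d["control_points"]), np.array(d["weights"]),
            transform_from_dict(d["affine"]), lam=d.get("lambda", 0.0),
            source_frame=d.get("source_frame"), target_frame=d.get("target_frame"),
        )
    if kind == "composite":
        return CompositeTransform([transform_from_dict(x) for x in d["transforms"]])
    raise ValueError(f"unknown transform type {kind!r}")


def save_transform(t, path) -> Path:
    Path(path).write_text(json.dumps(transform_to_dict(t), indent=2))
    return Path(path)


def load_transform(path):
    return transform_from_dict(json.loads(Path(path).read_text()))
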