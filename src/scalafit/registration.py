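"""Landmark-based similarity registration and cloud-to-cloud distances.

A membrane template is merged into a case scene with a least-squares
similarity transform fitted to the four corresponding landmarks (round
window center; lateral wall at 90, 180, 270 deg), the closed-form
Umeyama/Kabsch solution with det(R) = +1 enforced.  A proper rotation can
never absorb a side mismatch, so registering a left cochlea to a
right-side template leaves a large residual and raises a chirality
warning; the contralateral (mirrored) template should be used instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    ChiralityWarning,
    DegenerateGeometryError,
    EmptyCropError,
    ParameterError,
)
from .geometry import CochlearLandmarks, MembraneTemplate

__all__ = [
    "SimilarityTransform",
    "CloudDistanceResult",
    "fit_landmark_transform",
    "apply_transform",
    "crop_by_angle",
    "cloud_to_cloud_distance",
]


@dataclass(frozen=True)
class SimilarityTransform:
    """p -> scale * R @ p + t with R a proper rotation."""

    rotation: np.ndarray
    scale: float
    translation: np.ndarray
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise ParameterError("scale must be finite and > 0")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-9):
            raise ParameterError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-9):
            raise ParameterError("rotation must have determinant +1")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(np.eye(3), 1.0, np.zeros(3))

    def apply(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        out = self.scale * np.atleast_2d(p) @ self.rotation.T + self.translation
        return out[0] if single else out

    def inverse(self) -> "SimilarityTransform":
        rinv = self.rotation.T
        sinv = 1.0 / self.scale
        return SimilarityTransform(rinv, sinv, -sinv * rinv @ self.translation,
                                   self.rms_residual)

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return SimilarityTransform(
            self.rotation @ other.rotation,
            self.scale * other.scale,
            self.scale * self.rotation @ other.translation + self.translation,
        )


@dataclass(frozen=True)
class CloudDistanceResult:
    """Summary of nearest-neighbor distances between two clouds (mm)."""

    mean: float
    sd: float
    max: float
    per_point: np.ndarray
    direction: str = "source_to_target"


def _landmark_array(x) -> np.ndarray:
    if isinstance(x, CochlearLandmarks):
        return x.as_array()
    a = np.asarray(x, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3 or len(a) < 3:
        raise ParameterError("expected CochlearLandmarks or an (n>=3, 3) array")
    return a


def fit_landmark_transform(source, target,
                           allow_scale: bool = True) -> SimilarityTransform:
    """Least-squares similarity (or rigid) transform mapping ``source``
    landmarks onto ``target``.

    Minimizes sum ||s R p_i + t - q_i||^2 over the correspondences with
    det(R) = +1 enforced (Umeyama 1991).  If an improper (reflective) fit
    would reduce the residual by more than 10x, a :class:`ChiralityWarning`
    is emitted: the landmarks likely come from the contralateral side.
    """
    src = _landmark_array(source)
    dst = _landmark_array(target)
    if src.shape != dst.shape:
        raise ParameterError("source and target must have the same number of landmarks")
    n = len(src)
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    x, y = src - mu_s, dst - mu_d
    for pts, who in ((x, "source"), (y, "target")):
        sv = np.linalg.svd(pts, compute_uv=False)
        if sv[1] < 1e-9 * max(sv[0], 1.0):
            raise DegenerateGeometryError(f"{who} landmarks are collinear")

    cov = y.T @ x / n
    u, d, vt = np.linalg.svd(cov)
    sign = np.sign(np.linalg.det(u) * np.linalg.det(vt))
    var_src = (x ** 2).sum() / n

    def build(s3: float):
        smat = np.diag([1.0, 1.0, s3])
        rot = u @ smat @ vt
        scale = float((d * np.diag(smat)).sum() / var_src) if allow_scale else 1.0
        trans = mu_d - scale * rot @ mu_s
        res = dst - (scale * src @ rot.T + trans)
        rms = float(np.sqrt((res ** 2).sum() / n))
        return rot, scale, trans, rms

    # proper-rotation fit: force det(R) = +1 regardless of the data's chirality
    rot, scale, trans, rms = build(1.0 if sign >= 0 else -1.0)
    if sign < 0:
        # compare with the (disallowed) reflective fit to detect side mismatch
        refl = u @ vt
        s_refl = float(d.sum() / var_src) if allow_scale else 1.0
        t_refl = mu_d - s_refl * refl @ mu_s
        res = dst - (s_refl * src @ refl.T + t_refl)
        rms_refl = float(np.sqrt((res ** 2).sum() / n))
        if rms_refl < 0.1 * rms:
            warnings.warn(
                "a reflection fits these landmarks far better than a rotation "
                f"(rms {rms_refl:.3g} vs {rms:.3g} mm); the case is likely "
                "contralateral to the template - use the mirrored template",
                ChiralityWarning, stacklevel=2)
    return SimilarityTransform(rot, scale, trans, rms)


def apply_transform(transform: SimilarityTransform, points) -> np.ndarray:
    """Apply ``transform`` to one point or an (n, 3) array of points."""
    p = np.asarray(points, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ParameterError("points must be finite")
    return transform.apply(p)


def crop_by_angle(template: MembraneTemplate, min_deg: float,
                  max_deg: float) -> MembraneTemplate:
    """Restrict a template to insertion angles in [min_deg, max_deg].

    Faces with any vertex outside the window are dropped; unreferenced
    vertices are removed.  Stored landmarks are kept only when the crop
    still covers the full 0-270 deg landmark range.
    """
    if not min_deg < max_deg:
        raise ParameterError("need min_deg < max_deg")
    ang = template.angular_coord
    keep = (ang >= min_deg - 1e-9) & (ang <= max_deg + 1e-9)
    face_keep = keep[template.faces].all(axis=1)
    if not face_keep.any():
        raise EmptyCropError(
            f"crop [{min_deg}, {max_deg}] deg removes every face "
            f"(template spans {template.angular_span[0]:.1f}-"
            f"{template.angular_span[1]:.1f} deg)")
    faces = template.faces[face_keep]
    used = np.unique(faces)
    remap = np.full(template.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    out = template.copy()
    out.vertices = template.vertices[used]
    out.angular_coord = template.angular_coord[used]
    if template.width_frac is not None:
        out.width_frac = template.width_frac[used]
    out.faces = remap[faces]
    if not (min_deg <= 1e-9 and max_deg >= 270.0):
        out.landmarks = None
    return out


def _as_points(obj) -> np.ndarray:
    if isinstance(obj, MembraneTemplate):
        return obj.vertices
    a = np.asarray(obj, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3 or len(a) == 0:
        raise ParameterError("expected a non-empty (n, 3) point array or template")
    return a


def _one_way(source: np.ndarray, target, surface: bool) -> np.ndarray:
    if surface:
        from .meshquery import MeshQuery

        if not isinstance(target, MembraneTemplate):
            raise ParameterError("surface mode requires a MembraneTemplate target")
        return MeshQuery(target.vertices, target.faces).query(source).distance
    d, _ = cKDTree(_as_points(target)).query(source)
    return np.asarray(d)


def cloud_to_cloud_distance(source, target, direction: str = "source_to_target",
                            target_is_surface: bool = False) -> CloudDistanceResult:
    """Nearest-neighbor distance of ``source`` points to ``target``.

    The default compares point sets (the cloud/cloud distance of common
    mesh-processing tools); ``target_is_surface=True`` measures exact
    distance to the target triangulation instead.  ``direction='symmetric'``
    pools both directions (point-set mode only for the reverse leg).
    """
    src = _as_points(source)
    if direction not in ("source_to_target", "symmetric"):
        raise ParameterError("direction must be 'source_to_target' or 'symmetric'")
    d = _one_way(src, target, target_is_surface)
    if direction == "symmetric":
        back = _one_way(_as_points(target), source, False)
        d = np.concatenate([d, back])
    return CloudDistanceResult(
        mean=float(d.mean()), sd=float(d.std(ddof=1)) if len(d) > 1 else 0.0,
        max=float(d.max()), per_point=d, direction=direction)
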