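"""Parametric cochlear geometry and synthetic implanted-cochlea generation.

The cochlear duct mid-surface ("basilar membrane" in the loose sense that
includes the osseous spiral lamina) is modelled as a ribbon swept along a
logarithmic planar spiral ``r(theta) = a * exp(-b * theta)`` with a monotone,
piecewise-linear height profile pinned so that the rise over the first full
turn equals the cochlear height H360.  The coordinate convention is fixed and
right-handed: the modiolar axis is +z, the base plane is z = 0, theta = 0 at
the round-window center, and theta increases toward the apex.  A right
cochlea winds counterclockwise seen from the apex; a left cochlea is its
mirror image through the plane containing the modiolar axis and the 0 ray
(the xz-plane).

The synthetic generator stands in for the CT/CBCT image bank: it samples
cochlear dimensions from the population statistics (A = 9.1 +/- 0.30 mm,
B = 6.8 +/- 0.32 mm, H360 = 2.8 +/- 0.21 mm), builds the mid-surface,
implants a 16- or 20-contact electrode array with a prescribed translocation
pattern, and records per-electrode ground-truth scalar categories from the
construction offsets.  All units are millimetres and degrees.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .errors import (
    CoverageError,
    DegenerateGeometryError,
    ParameterError,
    TranslocationSpecError,
)

__all__ = [
    "SpiralParams",
    "CochlearLandmarks",
    "MembraneTemplate",
    "ElectrodeArray",
    "ArrayModel",
    "ARRAY_MODELS",
    "TranslocationSpec",
    "SyntheticCase",
    "CohortSettings",
    "spiral_radius",
    "spiral_height",
    "analytic_landmarks",
    "params_from_dimensions",
    "make_membrane_surface",
    "extract_landmarks",
    "mirror_template",
    "synth_electrode_array",
    "synth_case",
    "synth_cohort",
]

# Fraction of the basal spiral scale kept clear of the modiolar axis by the
# ribbon's inner edge; the duct width tapers apically where the log spiral
# decays below the nominal half-width (beyond ~540 deg for typical fits).
_INNER_RADIUS_FRACTION = 0.02

_SIDES = ("left", "right")


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SpiralParams:
    """Parameters of the spiral mid-surface of one cochlea.

    basal_radius_a : planar spiral scale ``a`` in mm.
    decay_b        : spiral tightening per radian (dimensionless).
    turns          : number of cochlear turns, 2.25 to 3.0.
    height_h360    : vertical rise of the duct mid-line over the first turn, mm.
    total_height   : mid-line height at the apex, mm (> height_h360).
    duct_width     : radial extent of the ribbon, lateral wall to modiolar
                     edge, mm.
    side           : "left" or "right".
    """

    basal_radius_a: float
    decay_b: float
    turns: float
    height_h360: float
    total_height: float
    duct_width: float
    side: str = "right"

    def __post_init__(self) -> None:
        vals = (self.basal_radius_a, self.decay_b, self.turns,
                self.height_h360, self.total_height, self.duct_width)
        if not all(np.isfinite(v) for v in vals):
            raise ParameterError("spiral parameters must be finite")
        if self.basal_radius_a <= 0 or self.decay_b <= 0 or self.duct_width <= 0:
            raise ParameterError("basal_radius_a, decay_b and duct_width must be > 0")
        if not (2.25 <= self.turns <= 3.0):
            raise ParameterError(f"turns must be in [2.25, 3.0], got {self.turns}")
        if not (0 < self.height_h360 < self.total_height):
            raise ParameterError("need 0 < height_h360 < total_height")
        if self.side not in _SIDES:
            raise ParameterError(f"side must be one of {_SIDES}")

    @property
    def theta_max(self) -> float:
        """Apical angular extent in radians."""
        return 2.0 * np.pi * self.turns


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float).reshape(3)
    if not np.all(np.isfinite(a)):
        raise ParameterError("landmark coordinates must be finite")
    return a


@dataclass(frozen=True)
class CochlearLandmarks:
    """The four registration landmarks of one cochlea (mm).

    rw_center is the round-window center (angular origin); lw90/lw180/lw270
    are lateral-wall points where the mid-turn line meets the outer wall at
    90, 180 and 270 degrees of insertion angle.
    """

    rw_center: np.ndarray
    lw90: np.ndarray
    lw180: np.ndarray
    lw270: np.ndarray

    NAMES = ("rw_center", "lw90", "lw180", "lw270")

    def __post_init__(self) -> None:
        for name in self.NAMES:
            object.__setattr__(self, name, _as_point(getattr(self, name)))
        pts = self.as_array()
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        if np.any(d[np.triu_indices(4, 1)] < 1e-9):
            raise DegenerateGeometryError("landmarks contain a coincident pair")
        centered = pts - pts.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        if s[1] < 1e-9 * max(s[0], 1.0):
            raise DegenerateGeometryError("landmarks are collinear")

    def as_array(self) -> np.ndarray:
        """Landmarks as a (4, 3) array in canonical order."""
        return np.stack([getattr(self, n) for n in self.NAMES])

    @classmethod
    def from_array(cls, pts) -> "CochlearLandmarks":
        pts = np.asarray(pts, dtype=float)
        if pts.shape != (4, 3):
            raise ParameterError("expected a (4, 3) landmark array")
        return cls(*pts)

    def transformed(self, transform) -> "CochlearLandmarks":
        """Landmarks mapped through any object with an ``apply(points)``."""
        return CochlearLandmarks.from_array(transform.apply(self.as_array()))


@dataclass
class MembraneTemplate:
    """Triangulated mid-surface of the cochlear duct plus its metadata.

    Face normals are oriented toward the scala vestibuli (+z-leaning in the
    canonical frame).  ``angular_coord`` stores the insertion angle (deg from
    the round window) of each vertex; ``width_frac`` its across-ribbon
    position in [-0.5, +0.5] with +0.5 the lateral (outer) edge.
    """

    vertices: np.ndarray
    faces: np.ndarray
    angular_coord: np.ndarray
    width_frac: Optional[np.ndarray] = None
    landmarks: Optional[CochlearLandmarks] = None
    index_value: Optional[float] = None
    side: str = "right"
    label: str = ""
    spiral_params: Optional[SpiralParams] = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.angular_coord = np.asarray(self.angular_coord, dtype=float)
        if self.width_frac is not None:
            self.width_frac = np.asarray(self.width_frac, dtype=float)
        n = len(self.vertices)
        if self.angular_coord.shape != (n,):
            raise ParameterError("angular_coord must have one value per vertex")
        if np.any(self.angular_coord < -1e-9):
            raise ParameterError("angular_coord must be non-negative")
        if self.side not in _SIDES:
            raise ParameterError(f"side must be one of {_SIDES}")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def angular_span(self) -> tuple:
        """(min, max) insertion angle covered by the mesh, degrees."""
        return float(self.angular_coord.min()), float(self.angular_coord.max())

    def copy(self) -> "MembraneTemplate":
        return dataclasses.replace(
            self,
            vertices=self.vertices.copy(),
            faces=self.faces.copy(),
            angular_coord=self.angular_coord.copy(),
            width_frac=None if self.width_frac is None else self.width_frac.copy(),
        )

    def transformed(self, transform) -> "MembraneTemplate":
        """Template mapped through a similarity/rigid transform.

        Angular coordinates and ribbon fractions are frame-invariant and kept;
        spiral provenance is dropped because the canonical frame is lost.
        """
        out = self.copy()
        out.vertices = np.asarray(transform.apply(self.vertices))
        if self.landmarks is not None:
            out.landmarks = self.landmarks.transformed(transform)
        out.spiral_params = None
        return out

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               process=False)


@dataclass(frozen=True)
class ElectrodeArray:
    """Ordered electrode contact centers, most basal first (mm)."""

    centers: np.ndarray
    contact_diameter: float
    model_name: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3 or len(c) < 1:
            raise ParameterError("centers must be a non-empty (n, 3) array")
        if not np.all(np.isfinite(c)):
            raise ParameterError("electrode centers must be finite")
        if len(c) > 1 and np.any(np.linalg.norm(np.diff(c, axis=0), axis=1) <= 0):
            raise ParameterError("consecutive electrode centers must be distinct")
        if not (self.contact_diameter > 0):
            raise ParameterError("contact_diameter must be > 0")
        object.__setattr__(self, "centers", c)

    @property
    def n_electrodes(self) -> int:
        return len(self.centers)

    def transformed(self, transform) -> "ElectrodeArray":
        return dataclasses.replace(self, centers=np.asarray(transform.apply(self.centers)))


@dataclass(frozen=True)
class ArrayModel:
    """Built-in electrode-array model: contact count, angular span covered at
    full insertion, contact diameter, and default insertion depth."""

    n_electrodes: int
    span_deg: float
    contact_diameter: float
    default_depth_deg: float


#: A perimodiolar-style 16-contact array and a lateral-wall-style 20-contact
#: array.  Spans/diameters are nominal; spacing is uniform in arc length.
ARRAY_MODELS = {
    "midscala_like": ArrayModel(16, 420.0, 0.7, 420.0),
    "evo_like": ArrayModel(20, 450.0, 0.5, 450.0),
}

_PATTERNS = ("none", "proximal_crossing", "distal_bending")


@dataclass(frozen=True)
class TranslocationSpec:
    """Prescribed translocation scenario for the simulator.

    ``proximal_crossing``: the array crosses the duct mid-plane near 180 deg
    of insertion and stays in the scala vestibuli beyond.
    ``distal_bending``: beyond 300 deg the array bends up against the
    membrane and rides it in an intermediate position.
    """

    pattern: str = "none"
    onset_angle: Optional[float] = None
    proximal_window: float = 45.0

    def __post_init__(self) -> None:
        if self.pattern not in _PATTERNS:
            raise TranslocationSpecError(f"pattern must be one of {_PATTERNS}")
        onset = self.onset_angle
        if self.pattern == "proximal_crossing":
            onset = 180.0 if onset is None else onset
            if abs(onset - 180.0) > self.proximal_window:
                raise TranslocationSpecError(
                    f"proximal crossing onset {onset} outside 180 +/- "
                    f"{self.proximal_window} deg")
        elif self.pattern == "distal_bending":
            onset = 310.0 if onset is None else onset
            if onset <= 300.0:
                raise TranslocationSpecError(
                    f"distal bending requires onset > 300 deg, got {onset}")
        object.__setattr__(self, "onset_angle", onset)

    @property
    def end_state(self) -> str:
        return {"none": "scala_tympani",
                "proximal_crossing": "scala_vestibuli",
                "distal_bending": "intermediate"}[self.pattern]


# ---------------------------------------------------------------------------
# closed-form spiral evaluation


def spiral_radius(params: SpiralParams, theta) -> np.ndarray:
    """Mid-line planar radius at angle ``theta`` (radians)."""
    return params.basal_radius_a * np.exp(-params.decay_b * np.asarray(theta, float))


def spiral_height(params: SpiralParams, theta) -> np.ndarray:
    """Mid-line height z at angle ``theta`` (radians).

    Linear with slope H360 / 2pi up to one turn, then linear again so the
    apex reaches ``total_height``; monotone by construction.
    """
    th = np.asarray(theta, dtype=float)
    h, top, tmax = params.height_h360, params.total_height, params.theta_max
    basal = h * th / (2.0 * np.pi)
    apical = h + (top - h) * (th - 2.0 * np.pi) / max(tmax - 2.0 * np.pi, 1e-12)
    return np.where(th <= 2.0 * np.pi, basal, apical)


def _midline(params: SpiralParams, theta) -> np.ndarray:
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    r = spiral_radius(params, th)
    y = r * np.sin(th)
    if params.side == "left":
        y = -y
    return np.column_stack([r * np.cos(th), y, spiral_height(params, th)])


def _surface_normal(params: SpiralParams, theta) -> np.ndarray:
    """Unit normal of the ribbon surface, oriented toward scala vestibuli
    (+z-leaning), at mid-line angle ``theta`` (radians)."""
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    r = spiral_radius(params, th)
    dr = -params.decay_b * r
    # piecewise-linear height: exact slope per segment
    h, top, tmax = params.height_h360, params.total_height, params.theta_max
    slope = np.where(th <= 2.0 * np.pi, h / (2 * np.pi),
                     (top - h) / max(tmax - 2 * np.pi, 1e-12))
    # tangents: d/dtheta of (r cos, r sin, z) and radial direction (cos, sin, 0)
    t_th = np.column_stack([dr * np.cos(th) - r * np.sin(th),
                            dr * np.sin(th) + r * np.cos(th),
                            slope])
    t_u = np.column_stack([np.cos(th), np.sin(th), np.zeros_like(th)])
    n = np.cross(t_th, t_u)
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    n[n[:, 2] < 0] *= -1.0
    if params.side == "left":
        n[:, 1] = -n[:, 1]
    return n


def analytic_landmarks(params: SpiralParams) -> CochlearLandmarks:
    """Closed-form landmark positions of the parametric surface.

    rw_center is the mid-line point at 0 deg; the lateral-wall landmarks are
    the outer ribbon edge (radius r + duct_width / 2) at 90/180/270 deg.
    """
    w2 = params.duct_width / 2.0
    pts = []
    for deg in (0.0, 90.0, 180.0, 270.0):
        th = np.deg2rad(deg)
        r = float(spiral_radius(params, th)) + (0.0 if deg == 0.0 else w2)
        y = r * np.sin(th)
        if params.side == "left":
            y = -y
        pts.append([r * np.cos(th), y, float(spiral_height(params, th))])
    rw, p90, p180, p270 = pts
    return CochlearLandmarks(rw, p90, p180, p270)


def params_from_dimensions(
    a_mm: float,
    b_mm: float,
    h360_mm: float,
    turns: float = 2.6,
    duct_width: float = 0.8,
    side: str = "right",
    total_height: Optional[float] = None,
) -> SpiralParams:
    """Solve spiral parameters so the analytic landmarks reproduce the
    measured distances A (round window to lateral wall at 180) and B
    (lateral wall 90 to 270), with the stated H360.

    The two chord equations in (a, b) are solved exactly (including the
    vertical components) by bracketing the decay rate.
    """
    for name, v in (("A", a_mm), ("B", b_mm), ("H360", h360_mm)):
        if not (np.isfinite(v) and v > 0):
            raise ParameterError(f"dimension {name} must be finite and > 0")
    if a_mm <= b_mm:
        raise ParameterError("expected distance A > distance B")
    half_h = h360_mm / 2.0
    if min(a_mm, b_mm) <= half_h:
        raise ParameterError("cochlear height inconsistent with A/B distances")
    pa = np.sqrt(a_mm ** 2 - half_h ** 2)   # planar span rw -> lw180
    pb = np.sqrt(b_mm ** 2 - half_h ** 2)   # planar span lw90 -> lw270
    w = duct_width
    if pa <= w:
        raise ParameterError("duct_width too large for distance A")

    def scale_for(b: float) -> float:
        # planar A equation: a + a e^{-b pi} + w/2 = pa
        return (pa - w / 2.0) / (1.0 + np.exp(-b * np.pi))

    def resid(b: float) -> float:
        a = scale_for(b)
        pred = a * (np.exp(-b * np.pi / 2) + np.exp(-3 * b * np.pi / 2)) + w
        return pred - pb

    lo, hi = 1e-4, 3.0
    if resid(lo) < 0 or resid(hi) > 0:
        raise ParameterError(
            f"no log-spiral fits A={a_mm}, B={b_mm} with duct_width={w}")
    decay = brentq(resid, lo, hi, xtol=1e-12)
    scale = scale_for(decay)
    if total_height is None:
        # apical rise continues at half the basal slope
        total_height = h360_mm * (1.0 + 0.5 * (turns - 1.0))
    return SpiralParams(scale, decay, turns, h360_mm, total_height, duct_width, side)


# ---------------------------------------------------------------------------
# surface construction and landmark extraction


def make_membrane_surface(
    params: SpiralParams,
    angular_step: float = 2.5,
    width_samples: int = 7,
    label: str = "",
) -> MembraneTemplate:
    """Triangulate the ribbon mid-surface swept along the spiral.

    ``angular_step`` is the sample spacing along the spiral in degrees
    (0 < step <= 15); ``width_samples`` (odd, >= 3) the number of samples
    across the ribbon, so the exact mid-line and both edges are vertices.
    """
    if not (0 < angular_step <= 15):
        raise ParameterError("angular_step must be in (0, 15] degrees")
    if width_samples < 3 or width_samples % 2 == 0:
        raise ParameterError("width_samples must be odd and >= 3")

    span_deg = params.turns * 360.0
    n_rings = int(round(span_deg / angular_step)) + 1
    theta_deg = np.linspace(0.0, span_deg, n_rings)
    th = np.deg2rad(theta_deg)
    r = spiral_radius(params, th)
    z = spiral_height(params, th)
    # taper the ribbon where the spiral decays below the nominal half-width,
    # keeping the inner edge clear of the modiolar axis
    w_eff = np.clip(2.0 * (r - _INNER_RADIUS_FRACTION * params.basal_radius_a),
                    0.05 * params.duct_width, params.duct_width)
    u = np.linspace(-0.5, 0.5, width_samples)

    rad = r[:, None] + u[None, :] * w_eff[:, None]          # (rings, width)
    x = rad * np.cos(th)[:, None]
    y = rad * np.sin(th)[:, None]
    if params.side == "left":
        y = -y
    zz = np.broadcast_to(z[:, None], rad.shape)
    verts = np.column_stack([x.ravel(), y.ravel(), zz.ravel()])
    angular = np.repeat(theta_deg, width_samples)
    wfrac = np.tile(u, n_rings)

    k = width_samples
    i = np.arange(n_rings - 1)[:, None] * k + np.arange(k - 1)[None, :]
    i = i.ravel()
    quads = np.column_stack([i, i + k, i + k + 1, i + 1])
    faces = np.concatenate([quads[:, [0, 1, 2]], quads[:, [0, 2, 3]]])

    # orient faces so normals lean toward +z (scala vestibuli side)
    v = verts
    fn = np.cross(v[faces[:, 1]] - v[faces[:, 0]], v[faces[:, 2]] - v[faces[:, 0]])
    if np.median(fn[:, 2]) < 0:
        faces = faces[:, ::-1]

    tmpl = MembraneTemplate(verts, faces, angular, wfrac, side=params.side,
                            label=label, spiral_params=params)
    tmpl.landmarks = extract_landmarks(tmpl)
    return tmpl


def _ring_spacing(angular: np.ndarray) -> float:
    uniq = np.unique(np.round(angular, 9))
    if len(uniq) < 2:
        raise CoverageError("template has a single angular ring")
    return float(np.median(np.diff(uniq)))


def extract_landmarks(template: MembraneTemplate) -> CochlearLandmarks:
    """Read the four registration landmarks off a template mesh.

    The lateral-wall points are the outer ribbon-edge vertices nearest 90,
    180 and 270 deg; the round-window center is the mid-line vertex nearest
    0 deg.  Raises :class:`CoverageError` if the mesh does not reach the
    requested angles.
    """
    if template.width_frac is None:
        raise ParameterError("template lacks width_frac; cannot locate ribbon edge")
    ang = template.angular_coord
    wf = template.width_frac
    step = _ring_spacing(ang)
    tol = 0.75 * step + 1e-9

    def pick(target: float, frac_mask: np.ndarray) -> np.ndarray:
        idx = np.flatnonzero(frac_mask)
        if idx.size == 0:
            raise CoverageError("template has no vertices at the requested ribbon edge")
        j = idx[np.argmin(np.abs(ang[idx] - target))]
        if abs(ang[j] - target) > tol:
            raise CoverageError(
                f"template does not cover {target} deg "
                f"(span {template.angular_span[0]:.1f}-{template.angular_span[1]:.1f})")
        return template.vertices[j]

    outer = wf >= wf.max() - 1e-9
    mid = np.abs(wf) <= np.abs(wf).min() + 1e-9
    rw = pick(0.0, mid)
    p90 = pick(90.0, outer)
    p180 = pick(180.0, outer)
    p270 = pick(270.0, outer)
    return CochlearLandmarks(rw, p90, p180, p270)


def mirror_template(template: MembraneTemplate) -> MembraneTemplate:
    """Contralateral (mirror-image) copy of a template.

    Reflection through the xz-plane (the plane of the modiolar axis and the
    0-deg ray); face winding is reversed so normals stay vestibuli-oriented.
    """
    out = template.copy()
    out.vertices[:, 1] *= -1.0
    out.faces = out.faces[:, ::-1]
    if template.landmarks is not None:
        pts = template.landmarks.as_array().copy()
        pts[:, 1] *= -1.0
        out.landmarks = CochlearLandmarks.from_array(pts)
    out.side = "left" if template.side == "right" else "right"
    if template.label.endswith("-mirrored"):
        out.label = template.label[: -len("-mirrored")]
    else:
        out.label = (template.label + "-mirrored") if template.label else "mirrored"
    if template.spiral_params is not None:
        out.spiral_params = dataclasses.replace(template.spiral_params, side=out.side)
    return out


# ---------------------------------------------------------------------------
# synthetic electrode arrays and ground truth


def _cap_fraction(signed_d: float, radius: float) -> float:
    # volume fraction of a sphere below the plane at signed distance d
    h = float(np.clip(signed_d, -radius, radius))
    a = radius - h
    return a * a * (3.0 * radius - a) / (4.0 * radius ** 3)


def _truth_category(signed_offset: float, radius: float) -> str:
    f = _cap_fraction(signed_offset, radius)
    if f >= 0.50:
        return "ST"
    if f >= 0.10:
        return "INT"
    return "SV"


def synth_electrode_array(
    template: MembraneTemplate,
    model_name: str,
    spec: TranslocationSpec,
    depth_angle: Optional[float] = None,
    seed: int = 0,
    *,
    clearance: float = 0.6,
    sv_clearance: float = 0.8,
    intermediate_offset: Optional[float] = None,
    center_jitter: float = 0.0,
):
    """Place an electrode array in a synthetic cochlea with known truth.

    Contacts are spaced uniformly in arc length along a path that follows
    the duct mid-line, offset along the local surface normal: ``-clearance``
    (scala tympani) for a clean insertion, ``+sv_clearance`` beyond the
    onset of a proximal crossing, and ``+intermediate_offset`` (default
    0.27 x contact radius, the distance midpoint of the intermediate band)
    beyond the onset of a distal bending.  Ground-truth categories are
    computed from these construction offsets, independently of the
    classification pipeline.

    Returns ``(ElectrodeArray, truth_calls)``.
    """
    params = template.spiral_params
    if params is None:
        raise ParameterError("template lacks spiral parameters; cannot synthesize")
    if model_name not in ARRAY_MODELS:
        raise ParameterError(
            f"unknown array model {model_name!r}; choose from {sorted(ARRAY_MODELS)}")
    model = ARRAY_MODELS[model_name]
    depth = model.default_depth_deg if depth_angle is None else float(depth_angle)
    span = template.angular_span[1]
    if depth > span + 1e-9:
        raise ParameterError(
            f"insertion depth {depth} deg exceeds template span {span:.1f} deg")
    basal = max(depth - model.span_deg, 5.0)
    if spec.pattern != "none":
        if not (basal < spec.onset_angle < depth):
            raise TranslocationSpecError(
                f"onset {spec.onset_angle} deg outside array extent "
                f"[{basal:.0f}, {depth:.0f}] deg")

    # arc-length parameterization of the mid-line
    th_fine = np.deg2rad(np.linspace(0.0, span, max(int(span * 2), 64)))
    pts = _midline(params, th_fine)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s_of = lambda deg: np.interp(np.deg2rad(deg), th_fine, s)
    targets = np.linspace(s_of(basal), s_of(depth), model.n_electrodes)
    theta_e = np.interp(targets, s, th_fine)
    deg_e = np.rad2deg(theta_e)

    radius = model.contact_diameter / 2.0
    if intermediate_offset is None:
        intermediate_offset = 0.27 * radius
    offsets = np.full(model.n_electrodes, -clearance)
    if spec.pattern == "proximal_crossing":
        offsets[deg_e > spec.onset_angle] = +sv_clearance
    elif spec.pattern == "distal_bending":
        offsets[deg_e > spec.onset_angle] = +intermediate_offset

    centers = _midline(params, theta_e) + offsets[:, None] * _surface_normal(params, theta_e)
    if center_jitter > 0:
        rng = np.random.default_rng(seed)
        centers = centers + rng.normal(0.0, center_jitter, centers.shape)
    truth = [_truth_category(d, radius) for d in offsets]
    array = ElectrodeArray(centers, model.contact_diameter, model_name)
    return array, truth


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class CohortSettings:
    """Population and noise settings for the synthetic cohort.

    Dimension distributions default to the pre-implantation patient
    population: A = 9.1 +/- 0.30 mm, B = 6.8 +/- 0.32 mm,
    H360 = 2.8 +/- 0.21 mm; turns uniform in [2.25, 3.0].  Landmark click
    noise is isotropic Gaussian (sigma in mm).  Pattern frequencies follow
    the cadaver study design: half the cases use the 16-contact
    perimodiolar-style model (7/15 with a proximal crossing), half the
    20-contact lateral-wall-style model (4/15 proximal, 4/15 distal).
    """

    mean_a: float = 9.1
    sd_a: float = 0.30
    mean_b: float = 6.8
    sd_b: float = 0.32
    mean_h360: float = 2.8
    sd_h360: float = 0.21
    turns_range: tuple = (2.25, 3.0)
    duct_width: float = 0.8
    angular_step: float = 5.0
    landmark_sigma: float = 0.1
    randomize_pose: bool = True
    clearance: float = 0.6
    sv_clearance: float = 0.8
    max_retries: int = 100

    # (model, pattern) sampling weights
    model_probs: tuple = (("midscala_like", 0.5), ("evo_like", 0.5))
    pattern_probs: tuple = (
        ("midscala_like", (("none", 8 / 15), ("proximal_crossing", 7 / 15))),
        ("evo_like", (("none", 7 / 15), ("proximal_crossing", 4 / 15),
                      ("distal_bending", 4 / 15))),
    )


@dataclass
class SyntheticCase:
    """One synthetic implanted cochlea with ground truth.

    ``template_truth`` lives in the canonical generator frame; ``pose`` is
    the rigid motion into the case (scanner) frame, in which
    ``landmarks_true``, ``landmarks_noisy`` and ``array`` are expressed.
    """

    case_id: str
    template_truth: MembraneTemplate
    pose: object
    landmarks_true: CochlearLandmarks
    landmarks_noisy: CochlearLandmarks
    array: ElectrodeArray
    truth_calls: list
    dims_truth: object
    model_name: str
    translocation: TranslocationSpec
    seed: int


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def synth_case(seed: int, settings: CohortSettings = CohortSettings(),
               case_id: Optional[str] = None, *,
               model_name: Optional[str] = None,
               pattern: Optional[str] = None,
               onset_angle: Optional[float] = None) -> SyntheticCase:
    """Generate one synthetic case, fully determined by ``seed``.

    ``model_name``, ``pattern`` and ``onset_angle`` override the seeded
    sampling when given (the sampling draws are still consumed, so a case
    keeps its dimensions whether or not a pattern is forced).
    """
    from .morphometry import CochlearDimensions
    from .registration import SimilarityTransform

    rng = np.random.default_rng(seed)
    s = settings
    dims = None
    for _ in range(s.max_retries):
        a = rng.normal(s.mean_a, s.sd_a)
        b = rng.normal(s.mean_b, s.sd_b)
        h = rng.normal(s.mean_h360, s.sd_h360)
        if a > 0 and b > 0 and h > 0 and a > b and min(a, b) > h / 2:
            dims = (a, b, h)
            break
    if dims is None:
        raise ParameterError("could not sample positive cochlear dimensions")
    a, b, h = dims
    turns = rng.uniform(*s.turns_range)
    side = "right" if rng.random() < 0.5 else "left"
    models, mp = zip(*s.model_probs)
    sampled_model = str(rng.choice(models, p=np.asarray(mp) / np.sum(mp)))
    model_name = model_name or sampled_model
    pat_table = dict(s.pattern_probs)[model_name]
    pats, pp = zip(*pat_table)
    sampled_pattern = str(rng.choice(pats, p=np.asarray(pp) / np.sum(pp)))
    pattern = pattern or sampled_pattern
    if onset_angle is not None:
        onset = float(onset_angle)
    elif pattern == "proximal_crossing":
        onset = 180.0
    elif pattern == "distal_bending":
        onset = float(rng.uniform(310.0, 355.0))
    else:
        onset = None
    spec = TranslocationSpec(pattern, onset)

    params = params_from_dimensions(a, b, h, turns=turns,
                                    duct_width=s.duct_width, side=side)
    cid = case_id or f"case-{seed}"
    template = make_membrane_surface(params, angular_step=s.angular_step, label=cid)
    dims_truth = CochlearDimensions(a, b, h)
    template.index_value = dims_truth.index("AoBH")

    array_seed = int(rng.integers(2 ** 31))
    array, truth = synth_electrode_array(
        template, model_name, spec, seed=array_seed,
        clearance=s.clearance, sv_clearance=s.sv_clearance)

    if s.randomize_pose:
        pose = SimilarityTransform(_random_rotation(rng), 1.0,
                                   rng.uniform(-20.0, 20.0, 3))
    else:
        pose = SimilarityTransform.identity()
    lm_true = template.landmarks.transformed(pose)
    noisy = lm_true.as_array() + rng.normal(0.0, s.landmark_sigma, (4, 3)) \
        if s.landmark_sigma > 0 else lm_true.as_array()
    return SyntheticCase(
        case_id=cid,
        template_truth=template,
        pose=pose,
        landmarks_true=lm_true,
        landmarks_noisy=CochlearLandmarks.from_array(noisy),
        array=array.transformed(pose),
        truth_calls=truth,
        dims_truth=dims_truth,
        model_name=model_name,
        translocation=spec,
        seed=seed,
    )


def synth_cohort(n: int, settings: CohortSettings = CohortSettings(),
                 seed: int = 0) -> list:
    """Generate ``n`` independent synthetic cases, reproducible under seed."""
    if n < 1:
        raise ParameterError("cohort size must be >= 1")
    master = np.random.default_rng(seed)
    case_seeds = master.integers(2 ** 31, size=n)
    return [synth_case(int(cs), settings, case_id=f"case-{i:03d}")
            for i, cs in enumerate(case_seeds)]
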