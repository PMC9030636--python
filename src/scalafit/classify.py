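"""Per-electrode scalar classification against a registered membrane template.

Each electrode contact is modelled as a sphere of the contact diameter.  The
fraction of the contact lying under the membrane (on the scala-tympani side)
is the volume fraction of that sphere cut off by the local tangent plane at
the nearest surface point — a closed-form, rotation-invariant
operationalization of "percent of the electrode under the membrane".  The
fixed clinical thresholds then assign the category:

* scala tympani (ST): fraction >= 50%
* intermediate (INT): 10% <= fraction < 50%
* scala vestibuli (SV): fraction < 10%

A chord (projected-length) alternative is available via ``method="chord"``.
Signed distances are positive toward the scala vestibuli; template normals
are oriented that way by construction (the loader checks and flips
inconsistent meshes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .errors import ParameterError
from .geometry import ElectrodeArray, MembraneTemplate
from .meshquery import MeshQuery
from .registration import SimilarityTransform

__all__ = [
    "CATEGORIES",
    "THRESHOLD_ST",
    "THRESHOLD_SV",
    "ScalarCall",
    "ArrayCall",
    "signed_distance_to_membrane",
    "fraction_under",
    "classify_electrode",
    "classify_array",
]

CATEGORIES = ("ST", "INT", "SV")

#: fraction-under thresholds: >= 0.50 is scala tympani, < 0.10 scala vestibuli
THRESHOLD_ST = 0.50
THRESHOLD_SV = 0.10

#: classification region of the cropped template; calls outside are flagged
EDGE_ANGLE_RANGE = (90.0, 540.0)

#: angular window the template is restricted to before nearest-point queries.
#: Apical turns of a coiled cochlea lie vertically close (the inter-turn gap
#: shrinks past 360 deg), so an electrode displaced toward the scala
#: vestibuli can otherwise be captured by the surface of the turn above it.
#: Arrays never insert beyond ~540 deg, so queries stay within one turn of
#: every contact.
QUERY_ANGLE_RANGE = (0.0, 570.0)


@dataclass(frozen=True)
class ScalarCall:
    """Scalar-position call for one electrode."""

    electrode_index: int
    signed_distance: float    # mm, positive toward scala vestibuli
    fraction_under: float     # of the contact volume, in [0, 1]
    category: str             # ST / INT / SV
    angle_deg: float          # insertion angle of the nearest surface point
    edge_extrapolated: bool = False


@dataclass(frozen=True)
class ArrayCall:
    """Per-array summary of scalar calls."""

    calls: tuple
    translocated: bool
    first_sv_angle: Optional[float]

    def categories(self) -> List[str]:
        return [c.category for c in self.calls]

    def counts(self) -> dict:
        cats = self.categories()
        return {c: cats.count(c) for c in CATEGORIES}

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "electrode_index": [c.electrode_index for c in self.calls],
                "angle_deg": [c.angle_deg for c in self.calls],
                "signed_distance_mm": [c.signed_distance for c in self.calls],
                "fraction_under": [c.fraction_under for c in self.calls],
                "category": [c.category for c in self.calls],
                "edge_flag": [c.edge_extrapolated for c in self.calls],
            }
        )

    def summary(self) -> dict:
        return {
            "translocated": self.translocated,
            "first_sv_angle": self.first_sv_angle,
            "counts": self.counts(),
        }


def signed_distance_to_membrane(points, template: MembraneTemplate,
                                query: Optional[MeshQuery] = None):
    """Signed distance(s) from point(s) to the template surface.

    Positive when the point lies on the scala-vestibuli side of the local
    tangent plane at its nearest surface point.  Returns
    ``(signed_mm, angle_deg, edge_flag)``; hits on a boundary edge of the
    (possibly cropped) ribbon are flagged edge-extrapolated but still
    returned.  Pass scalars or an (n, 3) array.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    q = query if query is not None else MeshQuery(template.vertices, template.faces)
    res = q.query(pts)
    side = np.einsum("ij,ij->i", pts - res.closest, q.face_normals[res.face_index])
    signed = np.where(side >= 0, res.distance, -res.distance)
    angle = np.einsum("ij,ij->i", res.barycentric,
                      template.angular_coord[q.faces[res.face_index]])
    if single:
        return float(signed[0]), float(angle[0]), bool(res.on_boundary[0])
    return signed, angle, res.on_boundary


def _midline_angles(template: MembraneTemplate, points: np.ndarray):
    """Insertion angle of each point, by projection onto the duct mid-line.

    The mid-line polyline lies in the surface and the surface normal is
    perpendicular to its tangent, so contacts offset along the normal
    project back to their own insertion angle with no first-order bias
    (unlike the nearest *surface* point, whose angle shifts with offset on
    a tilted ribbon).  Returns None when the template carries no ribbon
    coordinates.
    """
    if template.width_frac is None:
        return None
    mid = np.flatnonzero(np.abs(template.width_frac) <= 1e-9)
    if len(mid) < 2:
        return None
    order = np.argsort(template.angular_coord[mid])
    mv = template.vertices[mid[order]]                  # (K, 3)
    ma = template.angular_coord[mid[order]]
    a, b = mv[:-1], mv[1:]                              # segments
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    p = points[:, None, :] - a[None, :, :]              # (P, K-1, 3)
    t = np.clip(np.einsum("pki,ki->pk", p, ab) / np.maximum(denom, 1e-300),
                0.0, 1.0)
    foot = a[None] + t[..., None] * ab[None]
    d2 = ((points[:, None, :] - foot) ** 2).sum(-1)
    k = np.argmin(d2, axis=1)
    rows = np.arange(len(points))
    return ma[k] + t[rows, k] * (ma[k + 1] - ma[k])


def fraction_under(signed_d, radius: float):
    """Volume fraction of a spherical contact below the membrane plane.

    With h the signed distance clamped to [-radius, radius] and
    a = radius - h, the submerged spherical-cap fraction is
    a^2 (3 radius - a) / (4 radius^3): 1 fully under (scala tympani),
    0 fully over, exactly 1/2 for a centered contact.
    """
    if not (np.isfinite(radius) and radius > 0):
        raise ParameterError("contact radius must be finite and > 0")
    d = np.asarray(signed_d, dtype=float)
    h = np.clip(d, -radius, radius)
    a = radius - h
    f = a * a * (3.0 * radius - a) / (4.0 * radius ** 3)
    return float(f) if np.isscalar(signed_d) else f


def classify_electrode(fraction: float, t_st: float = THRESHOLD_ST,
                       t_sv: float = THRESHOLD_SV) -> str:
    """Category from the fraction under the membrane (boundaries inclusive
    exactly as defined clinically: >=50% ST, >=10% and <50% INT, <10% SV)."""
    if not (0.0 <= fraction <= 1.0):
        raise ParameterError(f"fraction must be in [0, 1], got {fraction}")
    if not 0 < t_sv < t_st <= 1:
        raise ParameterError("thresholds must satisfy 0 < t_sv < t_st <= 1")
    if fraction >= t_st:
        return "ST"
    if fraction >= t_sv:
        return "INT"
    return "SV"


def classify_array(array: ElectrodeArray, template: MembraneTemplate,
                   transform: SimilarityTransform,
                   t_st: float = THRESHOLD_ST, t_sv: float = THRESHOLD_SV,
                   method: str = "volume") -> ArrayCall:
    """Classify every electrode of ``array`` against a registered template.

    ``transform`` maps the template into the case frame; electrode centers
    are pulled back through its inverse, distances are measured in template
    frame and rescaled to case millimetres.  ``method='chord'`` replaces the
    spherical-cap volume fraction by the submerged diameter fraction.
    """
    if array.n_electrodes == 0:
        raise ParameterError("electrode array is empty")
    if method not in ("volume", "chord"):
        raise ParameterError("method must be 'volume' or 'chord'")
    if template.angular_span[1] > QUERY_ANGLE_RANGE[1]:
        from .registration import crop_by_angle

        template = crop_by_angle(template, *QUERY_ANGLE_RANGE)
    pts_t = transform.inverse().apply(array.centers)
    signed_t, angle, boundary = signed_distance_to_membrane(pts_t, template)
    midline_angle = _midline_angles(template, np.atleast_2d(pts_t))
    if midline_angle is not None:
        angle = midline_angle
    signed = transform.scale * signed_t   # back to case-frame mm
    radius = array.contact_diameter / 2.0
    if method == "volume":
        frac = fraction_under(signed, radius)
    else:
        frac = np.clip((radius - signed) / (2.0 * radius), 0.0, 1.0)
    lo, hi = EDGE_ANGLE_RANGE
    edge = boundary | (angle < lo) | (angle > hi)
    calls = tuple(
        ScalarCall(i, float(signed[i]), float(frac[i]),
                   classify_electrode(float(frac[i]), t_st, t_sv),
                   float(angle[i]), bool(edge[i]))
        for i in range(array.n_electrodes)
    )
    sv_angles = [c.angle_deg for c in calls if c.category == "SV"]
    return ArrayCall(calls, translocated=bool(sv_angles),
                     first_sv_angle=min(sv_angles) if sv_angles else None)
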