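"""Cochlear dimensions, morphometric indices, and the 5-template bank.

The three indices combine the basal-turn diameters A (round window to
lateral wall at 180 deg) and B (lateral wall 90 to 270 deg) with the
height H360: A*H360 (mm^2), A*B*H360 (mm^3) and (A/B)*H360 (mm).  The
ratio index (A/B)*H360 is the pipeline default; it drives both template
selection and bank construction.  The bank holds five templates per side,
picked so their index values sit at symmetric quantiles (default
10/30/50/70/90%) of the reference population's fitted Gaussian, with the
contralateral side obtained by mirroring.
"""

from __future__ import annotations

import logging
import warnings
from collections import namedtuple
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import BankError, DegenerateGeometryError, ParameterError, StatisticsError
from .geometry import CochlearLandmarks, MembraneTemplate, mirror_template

__all__ = [
    "INDEX_KINDS",
    "CochlearDimensions",
    "CochlearIndices",
    "IndexDistribution",
    "TemplateBank",
    "measure_dimensions",
    "compute_indices",
    "fit_index_distribution",
    "build_template_bank",
    "select_template",
]

log = logging.getLogger("scalafit")

INDEX_KINDS = ("AH", "ABH", "AoBH")


@dataclass(frozen=True)
class CochlearDimensions:
    """Distances A, B and the height H360 of one cochlea (mm)."""

    a: float
    b: float
    h360: float

    def __post_init__(self) -> None:
        for name, v in (("A", self.a), ("B", self.b), ("H360", self.h360)):
            if not (np.isfinite(v) and v > 0):
                raise ParameterError(f"dimension {name} must be finite and > 0")
        if self.a <= self.b:
            warnings.warn(
                f"distance A ({self.a:.2f}) <= B ({self.b:.2f}); expected A > B",
                UserWarning, stacklevel=3)

    def index(self, kind: str = "AoBH") -> float:
        return getattr(compute_indices(self), _FIELD[kind])


@dataclass(frozen=True)
class CochlearIndices:
    """The three morphometric indices of one cochlea."""

    i_ah: float     # A * H360, mm^2
    i_abh: float    # A * B * H360, mm^3
    i_aobh: float   # (A / B) * H360, mm


_FIELD = {"AH": "i_ah", "ABH": "i_abh", "AoBH": "i_aobh"}

IndexDistribution = namedtuple("IndexDistribution", ["mean", "sd", "shapiro_p"])


def measure_dimensions(landmarks: CochlearLandmarks, h360: float) -> CochlearDimensions:
    """Distances A and B from the landmarks, with the supplied height.

    A is the Euclidean distance from the round-window center to the lateral
    wall at 180 deg; B spans the lateral wall from 90 to 270 deg.  H360 is
    measured on an aligned image plane (or taken from simulator truth) and
    passed in as a scalar.
    """
    if not (np.isfinite(h360) and h360 > 0):
        raise ParameterError("h360 must be finite and > 0")
    a = float(np.linalg.norm(landmarks.rw_center - landmarks.lw180))
    b = float(np.linalg.norm(landmarks.lw90 - landmarks.lw270))
    if a < 1e-9 or b < 1e-9:
        raise DegenerateGeometryError("coincident landmark pair")
    return CochlearDimensions(a, b, h360)


def compute_indices(dims: CochlearDimensions) -> CochlearIndices:
    """The three indices; algebraically i_abh / i_ah = B and
    i_ah / i_aobh = B."""
    return CochlearIndices(
        i_ah=dims.a * dims.h360,
        i_abh=dims.a * dims.b * dims.h360,
        i_aobh=(dims.a / dims.b) * dims.h360,
    )


def fit_index_distribution(values: Sequence[float]) -> IndexDistribution:
    """Sample mean, sd and Shapiro-Wilk normality p-value of index values."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 3:
        raise StatisticsError("need at least 3 index values")
    sd = float(v.std(ddof=1))
    if np.all(v == v[0]):
        warnings.warn("index values are constant; distribution is degenerate",
                      UserWarning, stacklevel=2)
        return IndexDistribution(float(v.mean()), 0.0, float("nan"))
    p = float(stats.shapiro(v).pvalue)
    return IndexDistribution(float(v.mean()), sd, p)


@dataclass(frozen=True)
class TemplateBank:
    """Five membrane templates per side, ordered by index value."""

    right: tuple
    left: tuple
    index_kind: str
    selection_percentiles: tuple
    reference_mean: float
    reference_sd: float

    def templates(self, side: str) -> tuple:
        if side not in ("left", "right"):
            raise ParameterError("side must be 'left' or 'right'")
        bank = self.right if side == "right" else self.left
        if not bank:
            raise BankError(f"bank has no {side}-side templates")
        return bank

    @property
    def index_values(self) -> np.ndarray:
        return np.array([t.index_value for t in self.right])


def _nearest_without_replacement(targets: np.ndarray,
                                 values: np.ndarray) -> List[int]:
    """Greedy nearest-value assignment, processed in target order.

    Ties break toward the lower index value, for determinism.
    """
    available = list(range(len(values)))
    picks = []
    for t in targets:
        best = min(available, key=lambda i: (abs(values[i] - t), values[i]))
        picks.append(best)
        available.remove(best)
    return picks


def build_template_bank(
    candidates: Sequence[MembraneTemplate],
    index_kind: str = "AoBH",
    percentiles: Sequence[float] = (10, 30, 50, 70, 90),
    reference_values: Optional[Sequence[float]] = None,
) -> TemplateBank:
    """Pick 5 templates whose indices sit at the target quantiles of the
    reference population.

    A Gaussian is fitted to ``reference_values`` (the large patient-cohort
    index sample; defaults to the candidates' own indices), the 5 quantiles
    are computed, and for each the unused candidate with the nearest
    index value is taken.  Each pick is mirrored for the contralateral side.
    """
    if index_kind not in INDEX_KINDS:
        raise ParameterError(f"index_kind must be one of {INDEX_KINDS}")
    pct = tuple(float(p) for p in percentiles)
    if len(pct) != 5 or not all(0 < p < 100 for p in pct) or sorted(pct) != list(pct):
        raise ParameterError("percentiles must be 5 increasing values in (0, 100)")
    cands = list(candidates)
    values = np.array([t.index_value for t in cands], dtype=float)
    if np.any(~np.isfinite(values)):
        raise BankError("every candidate needs a finite index_value")
    if len(np.unique(values)) < 5:
        raise BankError("need at least 5 candidates with distinct index values")

    ref = values if reference_values is None else np.asarray(reference_values, float)
    mean, sd = float(ref.mean()), float(ref.std(ddof=1))
    if sd <= 0:
        raise BankError("reference index distribution is degenerate")
    targets = stats.norm.ppf(np.array(pct) / 100.0, loc=mean, scale=sd)

    picks = _nearest_without_replacement(targets, values)
    chosen = sorted((cands[i] for i in picks), key=lambda t: t.index_value)
    right, left = [], []
    for t in chosen:
        r = t if t.side == "right" else mirror_template(t)
        right.append(r)
        left.append(mirror_template(r))
    return TemplateBank(tuple(right), tuple(left), index_kind, pct, mean, sd)


def select_template(bank: TemplateBank, case_index: float,
                    side: str = "right") -> MembraneTemplate:
    """Bank template minimizing |index_value - case_index| for the side.

    Ties break toward the lower index; out-of-range case indices clamp to
    the nearest extreme template (with a log warning) so every case gets a
    template.
    """
    if not np.isfinite(case_index):
        raise ParameterError("case_index must be finite")
    templates = bank.templates(side)
    vals = np.array([t.index_value for t in templates])
    if case_index < vals.min() or case_index > vals.max():
        log.warning("case index %.3f outside bank range [%.3f, %.3f]; "
                    "clamping to nearest template", case_index, vals.min(), vals.max())
    best = min(range(len(templates)),
               key=lambda i: (abs(vals[i] - case_index), vals[i]))
    return templates[best]
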