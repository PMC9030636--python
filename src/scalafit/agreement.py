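"""Multi-rater agreement statistics for scalar-position calls.

Implements Fleiss' (1971) fixed-marginal kappa for tables of N items
(electrodes) rated by n raters into k categories, per-category kappas via
the standard binary (category-vs-rest) collapse, seeded bootstrap
confidence intervals over items, and the Pearson chi-squared comparison of
two intermediate-electrode proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .errors import ParameterError, StatisticsError, UndefinedKappaError

__all__ = [
    "RaterTable",
    "KappaResult",
    "fleiss_kappa",
    "per_category_kappa",
    "kappa_ci",
    "compare_intermediate_proportions",
]

DEFAULT_CATEGORIES = ("ST", "INT", "SV")


@dataclass(frozen=True)
class RaterTable:
    """Items x categories table of rater counts.

    ``counts[i, j]`` is the number of raters assigning item ``i`` to
    category ``j``; every row sums to the (constant) number of raters.
    """

    counts: np.ndarray
    categories: tuple = DEFAULT_CATEGORIES
    item_labels: Optional[tuple] = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] < 1 or c.shape[1] < 2:
            raise ParameterError("counts must be (items >= 1, categories >= 2)")
        if np.any(c < 0) or not np.allclose(c, np.round(c)):
            raise ParameterError("counts must be non-negative integers")
        c = c.astype(np.int64)
        row_sums = c.sum(axis=1)
        if len(np.unique(row_sums)) != 1:
            raise ParameterError("every item must be rated by the same number of raters")
        if row_sums[0] < 2:
            raise ParameterError("need at least 2 raters")
        if len(self.categories) != c.shape[1]:
            raise ParameterError("categories must match the table width")
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "categories", tuple(self.categories))
        if self.item_labels is not None:
            labels = tuple(self.item_labels)
            if len(labels) != c.shape[0]:
                raise ParameterError("item_labels must match the table height")
            object.__setattr__(self, "item_labels", labels)

    @property
    def n_items(self) -> int:
        return self.counts.shape[0]

    @property
    def n_raters(self) -> int:
        return int(self.counts[0].sum())

    @classmethod
    def from_assignments(cls, assignments, categories=DEFAULT_CATEGORIES,
                         item_labels=None) -> "RaterTable":
        """Build from an (items x raters) matrix of category labels."""
        arr = np.asarray(assignments)
        cats = tuple(categories)
        bad = set(arr.ravel()) - set(cats)
        if bad:
            raise ParameterError(
                f"unknown category labels {sorted(bad)}; valid: {list(cats)}")
        counts = np.stack([(arr == c).sum(axis=1) for c in cats], axis=1)
        return cls(counts, cats, item_labels)

    def collapse(self, category: str) -> "RaterTable":
        """Binary (category vs rest) view of the table."""
        if category not in self.categories:
            raise ParameterError(
                f"category {category!r} not in table categories {self.categories}")
        j = self.categories.index(category)
        rest = self.counts.sum(axis=1) - self.counts[:, j]
        return RaterTable(np.column_stack([self.counts[:, j], rest]),
                          (category, f"not_{category}"), self.item_labels)


@dataclass(frozen=True)
class KappaResult:
    """A kappa point estimate with optional confidence interval."""

    kappa: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    scope: str = "overall"
    n_items: int = 0
    n_raters: int = 0


def _kappa_value(counts: np.ndarray) -> float:
    n = counts[0].sum()                       # raters per item
    p_j = counts.sum(axis=0) / counts.sum()   # category proportions
    p_e = float((p_j ** 2).sum())
    p_i = ((counts ** 2).sum(axis=1) - n) / (n * (n - 1))
    p_bar = float(p_i.mean())
    if p_e >= 1.0 - 1e-15:
        raise UndefinedKappaError(
            "all ratings fall in a single category; chance agreement is 1")
    return (p_bar - p_e) / (1.0 - p_e)


def fleiss_kappa(table: RaterTable) -> KappaResult:
    """Fleiss' kappa of the full table.

    Per-item agreement P_i = (sum_j n_ij^2 - n) / (n (n - 1)), expected
    chance agreement P_e = sum_j p_j^2, and
    kappa = (mean P_i - P_e) / (1 - P_e).
    """
    if table.n_items < 2:
        raise StatisticsError("need at least 2 items for a kappa")
    return KappaResult(_kappa_value(table.counts), scope="overall",
                       n_items=table.n_items, n_raters=table.n_raters)


def per_category_kappa(table: RaterTable, category: str) -> KappaResult:
    """Category-wise kappa: Fleiss' kappa of the binary collapsed table."""
    res = fleiss_kappa(table.collapse(category))
    return KappaResult(res.kappa, scope=f"per_category:{category}",
                       n_items=res.n_items, n_raters=res.n_raters)


def kappa_ci(table: RaterTable, alpha: float = 0.05, method: str = "bootstrap",
             seed: int = 0, n_boot: int = 2000,
             category: Optional[str] = None):
    """Confidence interval for (overall or per-category) Fleiss' kappa.

    Default: seeded nonparametric bootstrap over items with a percentile
    interval; resamples whose kappa is undefined (single-category) are
    skipped.  ``method='asymptotic'`` uses the Fleiss large-sample standard
    error instead.  Fewer than 5 items: refused with a warning, returning
    (nan, nan).
    """
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    t = table if category is None else table.collapse(category)
    if t.n_items < 5:
        warnings.warn("too few items (< 5) for a kappa confidence interval",
                      UserWarning, stacklevel=2)
        return float("nan"), float("nan")
    if method == "asymptotic":
        return _asymptotic_ci(t, alpha)
    if method != "bootstrap":
        raise ParameterError("method must be 'bootstrap' or 'asymptotic'")
    rng = np.random.default_rng(seed)
    n = t.n_items
    reps = []
    for _ in range(n_boot):
        rows = rng.integers(0, n, size=n)
        try:
            reps.append(_kappa_value(t.counts[rows]))
        except UndefinedKappaError:
            continue
    if len(reps) < max(10, n_boot // 10):
        raise StatisticsError("bootstrap degenerate: almost all resamples "
                              "fell in a single category")
    lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def _asymptotic_ci(table: RaterTable, alpha: float):
    counts = table.counts
    n = table.n_raters
    n_items = table.n_items
    p_j = counts.sum(axis=0) / counts.sum()
    p_e = float((p_j ** 2).sum())
    kappa = _kappa_value(counts)
    num = p_e - (2 * n - 3) * p_e ** 2 + 2 * (n - 2) * float((p_j ** 3).sum())
    var = 2.0 * num / (n_items * n * (n - 1) * (1 - p_e) ** 2)
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(1 - alpha / 2)
    return kappa - z * se, kappa + z * se


def compare_intermediate_proportions(a: int, n1: int, b: int, n2: int,
                                     continuity_correction: bool = False):
    """Pearson chi-squared comparison of two proportions a/n1 vs b/n2.

    Builds the 2x2 table [[a, n1 - a], [b, n2 - b]] (1 df); continuity
    correction is off by default.  Returns ``(chi2, p_value)``.  Emits a
    warning when an expected cell count falls below 1.
    """
    for name, v in (("a", a), ("n1", n1), ("b", b), ("n2", n2)):
        if v < 0 or v != int(v):
            raise ParameterError(f"{name} must be a non-negative integer")
    if n1 == 0 or n2 == 0 or a > n1 or b > n2:
        raise ParameterError("need 0 <= a <= n1 and 0 <= b <= n2 with n1, n2 > 0")
    table = np.array([[a, n1 - a], [b, n2 - b]], dtype=float)
    col = table.sum(axis=0)
    if np.any(col == 0):
        # identical (degenerate) proportions: no evidence of a difference
        return 0.0, 1.0
    expected = np.outer(table.sum(axis=1), col) / table.sum()
    if np.any(expected < 1):
        warnings.warn("an expected cell count is below 1; the chi-squared "
                      "approximation is unreliable", UserWarning, stacklevel=2)
    res = stats.chi2_contingency(table, correction=continuity_correction)
    return float(res.statistic), float(res.pvalue)
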