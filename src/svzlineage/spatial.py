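"""In situ spot quantification along a normalized ventral -> dorsal axis.

Spot positions are projected onto a measurement polyline drawn from the
ventral-most extent of the lateral-wall V-SVZ to the dorso-lateral tip of
the wedge; the normalized arclength t in [0,1] of the nearest point defines
each spot's axis coordinate. The dorsal domain is the most dorsal third
(t >= 2/3, boundary inclusive); the ventral domain is the rest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import LineString, Point

DORSAL_BOUNDARY = 2.0 / 3.0


@dataclass
class AxisPolyline:
    """Ordered 2-D vertices, ventral-most point to dorso-lateral wedge tip."""

    vertices: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 2:
            raise ValueError("axis needs at least 2 vertices")
        seg = np.diff(self.vertices, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) <= 0):
            raise ValueError("axis arclength must be strictly increasing")

    @property
    def line(self) -> LineString:
        return LineString(self.vertices)

    @property
    def length(self) -> float:
        return self.line.length


def normalize_positions(spots: pd.DataFrame, axis: AxisPolyline) -> pd.DataFrame:
    """Assign t = arclength of the nearest polyline point / total arclength.

    Nearest point by orthogonal projection onto segments, clamped to
    segment ends (shapely's linear referencing).
    """
    line = axis.line
    total = line.length
    if total <= 0:
        raise ValueError("degenerate zero-length axis")
    t = np.array(
        [line.project(Point(x, y)) / total for x, y in zip(spots["x"], spots["y"])]
    )
    out = spots.copy()
    out["t"] = np.clip(t, 0.0, 1.0)
    return out


def density_profile(
    t: Sequence[float], n_bins: int = 50
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Histogram density of axis positions over [0, 1] plus the sample median.

    Returns (density, bin_edges, median).
    """
    t = np.asarray(t, float)
    if t.size == 0:
        raise ValueError("need at least one spot")
    density, edges = np.histogram(t, bins=n_bins, range=(0.0, 1.0), density=True)
    return density, edges, float(np.median(t))


def domain_assign(t) -> np.ndarray:
    """'dorsal' iff t >= 2/3 (most dorsal third, boundary inclusive)."""
    t = np.atleast_1d(np.asarray(t, float))
    if ((t < 0) | (t > 1)).any():
        raise ValueError("t must lie in [0, 1]")
    return np.where(t >= DORSAL_BOUNDARY, "dorsal", "ventral")


def colabel_fraction(
    flags: pd.DataFrame,
    domains: Sequence[str],
    numerator: str,
    denominator: str,
) -> Dict[str, float]:
    """Per-domain percentage of denominator-positive spots that are also
    numerator-positive, rounded to two decimals (e.g. 97.67)."""
    domains = np.asarray(domains)
    out: Dict[str, float] = {}
    for dom in pd.unique(domains):
        m = domains == dom
        den = flags.loc[m, denominator].to_numpy(bool)
        if den.sum() == 0:
            warnings.warn(f"domain {dom} has no {denominator}+ spots; omitted")
            continue
        num = flags.loc[m, numerator].to_numpy(bool)
        out[dom] = round(100.0 * (num & den).sum() / den.sum(), 2)
    return out


def two_group_ttest(
    values_a: Sequence[float],
    values_b: Sequence[float],
    equal_var: bool = True,
) -> Tuple[float, float]:
    """Two-sample two-sided t test (pooled variance by default, Welch
    optional). Zero pooled variance with equal means gives (0, 1)."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(np.concatenate([a, b])) == 0:
        return 0.0, 1.0
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    t, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(p):
        p = 1.0
    return t, p
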