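"""Alpha-shape morphometry of active-zone clusters.

The footprint of an AZ is measured as the area of its 2D alpha shape:
Delaunay-triangulate the member localizations and keep every triangle
whose squared circumradius is at most alpha (alpha thus carries nm²
units, and alpha -> infinity recovers the convex hull).  The alpha
parameter is selected per dye by sweeping alpha = x² nm² for
x = 5, 10, ..., 200 and taking the first grid value at which the median
AZ area grows by less than 5% relative to the previous step — beyond
that point the shape has stopped filling in genuine structure and is
merely inflating.

AZs with area <= 0.03 µm² or >= 0.3 µm² are excluded from analysis
(too small to be a genuine AZ, or likely a merge of several).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

from .loc_io import LocalizationTable
from .segmentation import Cluster

__all__ = [
    "AlphaCurve",
    "AlphaSelectionError",
    "DEFAULT_ALPHA_GRID",
    "AREA_WINDOW_UM2",
    "alpha_shape_area",
    "select_alpha",
    "apply_area_filter",
    "az_summary",
]

#: alpha = x² nm² for x from 5 to 200 nm in steps of 5
DEFAULT_ALPHA_GRID: tuple[float, ...] = tuple(float(x) ** 2 for x in range(5, 205, 5))

#: exclusion window for AZ areas (µm², both bounds excluded)
AREA_WINDOW_UM2: tuple[float, float] = (0.03, 0.3)


class AlphaSelectionError(RuntimeError):
    """No alpha step fell below the increase threshold; carries the curve."""

    def __init__(self, message: str, curve: "AlphaCurve | None" = None):
        super().__init__(message)
        self.curve = curve


@dataclass
class AlphaCurve:
    """Median AZ area versus alpha, and the selected alpha."""

    alphas: np.ndarray            # nm², strictly increasing
    median_area: np.ndarray       # nm²
    q25_area: np.ndarray
    q75_area: np.ndarray
    pct_increase: np.ndarray      # % per step; first entry NaN
    selected_alpha: float | None  # nm²
    threshold: float = 5.0        # %

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "alpha_nm2": self.alphas,
            "median_area_nm2": self.median_area,
            "q25_area_nm2": self.q25_area,
            "q75_area_nm2": self.q75_area,
            "pct_increase": self.pct_increase,
        })


def _triangle_geometry(points: np.ndarray):
    """(areas, squared circumradii) of all Delaunay triangles, or None if
    the point set is degenerate (fewer than 3 distinct points, collinear)."""
    pts = np.asarray(points, float)
    if len(pts) < 3:
        return None
    try:
        tri = Delaunay(pts)
    except QhullError:
        return None
    simplices = pts[tri.simplices]          # (m, 3, 2)
    a = simplices[:, 0]
    b = simplices[:, 1]
    c = simplices[:, 2]
    # twice the signed area via the cross product
    cross = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - \
            (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
    areas = 0.5 * np.abs(cross)
    la2 = np.sum((b - c) ** 2, axis=1)
    lb2 = np.sum((a - c) ** 2, axis=1)
    lc2 = np.sum((a - b) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        # R = abc / (4K)  =>  R² = a²b²c² / (16 K²)
        r2 = np.where(areas > 0, la2 * lb2 * lc2 / (16.0 * areas**2), np.inf)
    return tri, areas, r2


def alpha_shape_area(points, alpha: float, with_boundary: bool = True):
    """Area (nm²) and boundary of the 2D alpha shape of a point set.

    Keeps Delaunay triangles with squared circumradius <= ``alpha``
    (nm²).  Degenerate inputs (fewer than 3 points, all collinear, or no
    triangle surviving) give area 0 and no boundary, never an exception.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    geom = _triangle_geometry(points)
    if geom is None:
        return 0.0, None
    tri, areas, r2 = geom
    keep = r2 <= alpha
    area = float(areas[keep].sum())
    boundary = None
    if with_boundary and keep.any():
        import shapely
        from shapely.geometry import Polygon

        pts = np.asarray(points, float)
        polys = [Polygon(pts[s]) for s in tri.simplices[keep]]
        boundary = shapely.union_all(polys)
    return area, boundary


def _areas_over_grid(point_sets, alphas: np.ndarray) -> np.ndarray:
    """(n_sets, n_alphas) alpha-shape areas, triangulating each set once."""
    out = np.zeros((len(point_sets), len(alphas)))
    for i, pts in enumerate(point_sets):
        geom = _triangle_geometry(pts)
        if geom is None:
            continue
        _, areas, r2 = geom
        order = np.argsort(r2, kind="stable")
        sorted_r2 = r2[order]
        cum = np.concatenate([[0.0], np.cumsum(areas[order])])
        idx = np.searchsorted(sorted_r2, alphas, side="right")
        out[i] = cum[idx]
    return out


def select_alpha(point_sets, alphas=DEFAULT_ALPHA_GRID,
                 threshold: float = 5.0) -> AlphaCurve:
    """Sweep alpha over the grid and pick the first below-threshold step.

    For each alpha the median AZ area is taken across all point sets
    (pooled over images of one dye).  The percent increase at step k is
    ``100 * (median_k - median_{k-1}) / median_{k-1}``; the selected
    alpha is the first grid value whose increase falls below
    ``threshold``.  Raises :class:`AlphaSelectionError` (carrying the
    full curve) if no step qualifies.
    """
    if len(point_sets) == 0:
        raise ValueError("need at least one AZ point set")
    alphas = np.asarray(sorted(float(a) for a in alphas))
    if len(alphas) < 2:
        raise ValueError("alpha grid needs at least two values")
    areas = _areas_over_grid(point_sets, alphas)
    med = np.median(areas, axis=0)
    q25 = np.percentile(areas, 25, axis=0)
    q75 = np.percentile(areas, 75, axis=0)

    pct = np.full(len(alphas), np.nan)
    for k in range(1, len(alphas)):
        prev, cur = med[k - 1], med[k]
        if prev == 0:
            pct[k] = 0.0 if cur == 0 else np.inf
        else:
            pct[k] = 100.0 * (cur - prev) / prev

    selected = None
    for k in range(1, len(alphas)):
        if pct[k] < threshold:
            selected = float(alphas[k])
            break
    curve = AlphaCurve(alphas, med, q25, q75, pct, selected, threshold)
    if selected is None:
        raise AlphaSelectionError(
            f"no alpha step showed a median-area increase below {threshold}%",
            curve=curve)
    return curve


def apply_area_filter(records: pd.DataFrame,
                      window_um2: tuple[float, float] = AREA_WINDOW_UM2
                      ) -> pd.DataFrame:
    """Set the ``kept`` flag: strictly inside the area window.

    Areas <= the lower bound or >= the upper bound are excluded, so the
    predicate is ``lo < area < hi`` and applying the filter twice equals
    applying it once.
    """
    lo, hi = window_um2
    out = records.copy()
    area = out["area_um2"].to_numpy(float)
    out["kept"] = (area > lo) & (area < hi)
    return out


def az_summary(clusters: list[Cluster], table: LocalizationTable,
               alpha: float, window_um2: tuple[float, float] = AREA_WINDOW_UM2
               ) -> tuple[pd.DataFrame, dict]:
    """Per-AZ localization counts and alpha-shape areas, plus group stats.

    Returns a records DataFrame (az_id, n_localizations, area_um2, kept)
    with areas at the given alpha and the exclusion filter applied, and a
    dict of median/quartiles over the kept AZs.
    """
    xy = table.xy
    rows = []
    for cl in clusters:
        area_nm2, boundary = alpha_shape_area(xy[cl.members], alpha,
                                              with_boundary=False)
        cl.area_nm2 = area_nm2
        rows.append((cl.label, cl.n_localizations, area_nm2 / 1e6))
    records = pd.DataFrame(rows, columns=["az_id", "n_localizations", "area_um2"])
    records["kept"] = False
    if len(records):
        records = apply_area_filter(records, window_um2)
    kept = records[records["kept"]] if len(records) else records
    stats = {}
    for col, name in (("n_localizations", "locs_per_az"), ("area_um2", "az_area_um2")):
        if len(kept):
            vals = kept[col].to_numpy(float)
            stats[name] = {
                "median": float(np.median(vals)),
                "q25": float(np.percentile(vals, 25)),
                "q75": float(np.percentile(vals, 75)),
                "n": int(len(vals)),
            }
        else:
            stats[name] = {"median": float("nan"), "q25": float("nan"),
                           "q75": float("nan"), "n": 0}
    return records, stats
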