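"""Ripley's-H nanocluster radii and second-level subcluster extraction.

Within a single AZ, the scaffold protein is organised in nanoscale
subclusters (SCs).  Their characteristic radius is read from Ripley's
H function of the AZ's localizations:

    K(r) = A * sum_{i != j} 1(d_ij <= r) / (n (n - 1))
    L(r) = sqrt(K(r) / pi)
    H(r) = L(r) - r

computed without edge correction, with the AZ's alpha-shape area as the
reference area A.  For a homogeneous (Poisson) pattern H stays near 0;
clustering at a characteristic scale makes H peak near the cluster
radius.  Per-AZ curves are averaged per dye before the maximum is read
off, with ties broken toward smaller radii.

SCs themselves are extracted by a second-level HDBSCAN run on the
members of each AZ, with parameters calibrated per dye so that the
median SC radius matches the H-function maximum
(:func:`calibrate_sc_params`).  An SC's radius is its equivalent-circle
radius sqrt(area / pi), from the alpha-shape area at alpha = 300 nm².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

from .morphometry import alpha_shape_area
from .segmentation import Cluster, ClusteringParams, cluster_labels

__all__ = [
    "HCurve",
    "ScResult",
    "CalibrationError",
    "DEFAULT_R_GRID",
    "SC_ALPHA_NM2",
    "SC_PARAMS_BY_DYE",
    "ripley_k",
    "ripley_h",
    "average_h_and_max",
    "subcluster",
    "calibrate_sc_params",
]

#: radius grid for H functions: 0-150 nm in 1 nm steps
DEFAULT_R_GRID: np.ndarray = np.arange(0.0, 151.0, 1.0)

#: alpha used for SC alpha-shape areas, all dyes
SC_ALPHA_NM2: float = 300.0

#: second-level HDBSCAN parameters used per dye in the reference analysis
SC_PARAMS_BY_DYE: dict[str, ClusteringParams] = {
    "AF647": ClusteringParams(22, 5),
    "CF568": ClusteringParams(44, 11),
    "CF583R": ClusteringParams(15, 3),
}


class CalibrationError(RuntimeError):
    """No parameter pair on the search grid produced any subcluster."""


@dataclass
class HCurve:
    """Ripley's K/L/H on a radius grid for one point pattern (or a mean)."""

    r: np.ndarray          # nm
    k: np.ndarray          # nm²
    n_points: int
    area: float            # reference area A (nm²)

    @property
    def l(self) -> np.ndarray:
        return np.sqrt(self.k / np.pi)

    @property
    def h(self) -> np.ndarray:
        return self.l - self.r

    @property
    def h_max_radius(self) -> float:
        """argmax_r H(r); ties go to the smallest r."""
        return float(self.r[int(np.argmax(self.h))])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"r_nm": self.r, "K_nm2": self.k,
                             "L_nm": self.l, "H_nm": self.h})


def ripley_k(points, r_grid, area: float, neighbors=None,
             periodic: float | None = None) -> np.ndarray:
    """Uncorrected Ripley K on a radius grid.

    With the defaults this is the plain estimator
    ``K(r) = area * sum_{i != j} 1(d_ij <= r) / (n (n-1))`` over the
    given points — no edge correction, as used for AZ analysis.

    ``periodic`` (a box side length L) switches to minimum-image
    (torus) distances on [0, L)²; with a fixed-n uniform pattern this
    makes the estimator exactly unbiased (E[K] = pi r²), which is how
    the Poisson-null reference curves are produced.

    If ``neighbors`` is given (a superset of ``points``, e.g. all points
    of a pattern of which ``points`` is an interior subsample), pairs are
    counted from each point to every neighbor and normalized by
    ``n_points * (n_neighbors - 1)``, with ``area`` the full pattern
    window (minus-sampling; approximately unbiased when the subsample
    margin exceeds max(r)).
    """
    r_grid = np.asarray(r_grid, float)
    pts = np.asarray(points, float)
    if area <= 0:
        raise ValueError("reference area must be positive")
    n = len(pts)
    if neighbors is None:
        if n < 2:
            raise ValueError("Ripley K needs at least 2 points")
        if periodic is None:
            d = np.sort(pdist(pts))
        else:
            diff = np.abs(pts[:, None, :] - pts[None, :, :])
            diff = np.minimum(diff, periodic - diff)
            dmat = np.hypot(diff[..., 0], diff[..., 1])
            d = np.sort(dmat[np.triu_indices(n, k=1)])
        counts = 2.0 * np.searchsorted(d, r_grid, side="right")
        return area * counts / (n * (n - 1))
    nb = np.asarray(neighbors, float)
    if n < 1 or len(nb) < 2:
        raise ValueError("need >= 1 point and >= 2 neighbors")
    d = np.sort(cdist(pts, nb), axis=None)
    # each point matches itself once at distance 0 within the neighbor set
    counts = np.searchsorted(d, r_grid, side="right") - n
    return area * counts / (n * (len(nb) - 1))


def ripley_h(points, r_grid=None, area: float | None = None,
             neighbors=None) -> HCurve:
    """H curve of one point pattern; see :func:`ripley_k` for the estimator.

    ``area`` defaults to nothing — pass the AZ's alpha-shape area (the
    reference area strongly scales K).  Requires >= 2 points.
    """
    if r_grid is None:
        r_grid = DEFAULT_R_GRID
    pts = np.asarray(points, float)
    if len(pts) < 2:
        raise ValueError("H function undefined for fewer than 2 points")
    if area is None:
        raise ValueError("reference area is required")
    k = ripley_k(pts, r_grid, area, neighbors=neighbors)
    return HCurve(r=np.asarray(r_grid, float), k=k, n_points=len(pts), area=area)


def average_h_and_max(curves: list[HCurve]) -> tuple[HCurve, float]:
    """Pointwise mean of H over AZs and the radius of its maximum.

    All curves must share the radius grid.  The returned mean curve
    stores K back-computed from the mean H (so its ``h`` property is the
    pointwise mean); ``h_max_radius`` breaks ties toward smaller r.
    """
    if not curves:
        raise ValueError("no H curves to average")
    r = curves[0].r
    for c in curves[1:]:
        if len(c.r) != len(r) or not np.allclose(c.r, r):
            raise ValueError("H curves must share a common radius grid")
    mean_h = np.mean([c.h for c in curves], axis=0)
    mean_l = mean_h + r
    mean_k = np.pi * mean_l**2
    mean_curve = HCurve(r=r, k=mean_k,
                        n_points=int(np.mean([c.n_points for c in curves])),
                        area=float(np.mean([c.area for c in curves])))
    return mean_curve, mean_curve.h_max_radius


@dataclass
class ScResult:
    """Subclusters of one AZ: assignments plus per-SC morphometry."""

    az_label: int
    clusters: list[Cluster]
    table: pd.DataFrame     # sc_id, n_localizations, area_nm2, radius_nm

    @property
    def sc_count(self) -> int:
        return len(self.clusters)


def subcluster(az_points, params: ClusteringParams,
               sc_alpha: float = SC_ALPHA_NM2, az_label: int = 0,
               with_boundary: bool = False) -> ScResult:
    """Second-level HDBSCAN on one AZ's localizations.

    Each subcluster gets an alpha-shape area at ``sc_alpha`` (300 nm²)
    and the equivalent-circle radius sqrt(area / pi).  An AZ smaller
    than the minimum cluster size yields zero SCs, which is valid.
    Boundary polygons are only built on request (``with_boundary``).
    """
    pts = np.asarray(az_points, float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        labels = cluster_labels(pts, params)
    clusters, rows = [], []
    for lab in np.unique(labels):
        if lab < 0:
            continue
        members = np.nonzero(labels == lab)[0]
        area, boundary = alpha_shape_area(pts[members], sc_alpha,
                                          with_boundary=with_boundary)
        cl = Cluster(label=int(lab), members=members, level="SC",
                     area_nm2=area, boundary=boundary)
        clusters.append(cl)
        rows.append((int(lab), len(members), area, float(np.sqrt(area / np.pi))))
    table = pd.DataFrame(rows, columns=["sc_id", "n_localizations",
                                        "area_nm2", "radius_nm"])
    return ScResult(az_label=az_label, clusters=clusters, table=table)


def _default_calibration_grid() -> list[tuple[int, int]]:
    """Coarse (min_cluster_size, min_samples) pairs spanning mcs 3-60,
    ms 2-mcs; a tractable subset of the exhaustive rectangle."""
    mcs_values = range(3, 61, 3)
    ms_ladder = (2, 3, 5, 7, 9, 11, 15, 19, 25)
    return [(mcs, ms) for mcs in mcs_values for ms in ms_ladder if ms <= mcs]


def calibrate_sc_params(az_point_sets, target_radius: float,
                        grid: list[tuple[int, int]] | None = None,
                        sc_alpha: float = SC_ALPHA_NM2
                        ) -> tuple[ClusteringParams, float, pd.DataFrame]:
    """Find SC-level HDBSCAN parameters matching a target SC radius.

    Grid-searches (min_cluster_size, min_samples) pairs, scoring each by
    the absolute difference between the median equivalent-circle SC
    radius (pooled over the given AZs) and ``target_radius`` (typically
    the H-function maximum).  Ties break toward smaller
    min_cluster_size, then smaller min_samples.  Returns the winning
    parameters, the achieved median radius, and the full search table.
    """
    if target_radius <= 0:
        raise ValueError("target_radius must be positive")
    if len(az_point_sets) == 0:
        raise ValueError("need at least one AZ")
    if grid is None:
        grid = _default_calibration_grid()
    grid = sorted(set((int(a), int(b)) for a, b in grid))

    rows = []
    for mcs, ms in grid:
        params = ClusteringParams(mcs, ms)
        radii = []
        for pts in az_point_sets:
            res = subcluster(pts, params, sc_alpha=sc_alpha)
            radii.extend(res.table["radius_nm"].tolist())
        if radii:
            med = float(np.median(radii))
            rows.append((mcs, ms, med, abs(med - target_radius), len(radii)))
    if not rows:
        raise CalibrationError(
            f"no (min_cluster_size, min_samples) pair in the {len(grid)}-point "
            f"grid produced any subcluster")
    table = pd.DataFrame(rows, columns=["min_cluster_size", "min_samples",
                                        "median_radius_nm", "abs_error_nm", "n_sc"])
    # ties: smallest error, then smaller mcs, then smaller ms
    best = table.sort_values(["abs_error_nm", "min_cluster_size", "min_samples"],
                             kind="stable").iloc[0]
    params = ClusteringParams(int(best["min_cluster_size"]), int(best["min_samples"]))
    return params, float(best["median_radius_nm"]), table
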