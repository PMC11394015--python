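"""Density-based extraction of active zones from localization point clouds.

AZs are recovered as HDBSCAN clusters of the (x, y) positions — frames
and intensities play no role at this stage.  The two free parameters,
``min_cluster_size`` and ``min_samples``, default to (100, 25), a
combination that sits on a broad plateau of the cluster-count landscape;
:func:`parameter_sweep` maps that landscape over the standard grids so
the plateau can be verified for any data set.

The same machinery runs at the subcluster level (smaller parameters on
the members of a single AZ); see :mod:`azstorm.nanocluster`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN as _SkHDBSCAN

from .loc_io import LocalizationTable

__all__ = [
    "ClusteringParams",
    "Cluster",
    "SweepResult",
    "NOISE_LABEL",
    "DEFAULT_MCS_GRID",
    "DEFAULT_MS_GRID",
    "cluster_localizations",
    "cluster_labels",
    "parameter_sweep",
]

NOISE_LABEL = -1

#: sweep grids for the two HDBSCAN parameters:
#: minimum cluster size 10-90 step 10 then 100-500 step 100;
#: minimum samples 2, 5-25 step 5, then 30-100 step 10
DEFAULT_MCS_GRID: tuple[int, ...] = tuple(range(10, 100, 10)) + tuple(range(100, 600, 100))
DEFAULT_MS_GRID: tuple[int, ...] = (2,) + tuple(range(5, 30, 5)) + tuple(range(30, 110, 10))


@dataclass(frozen=True)
class ClusteringParams:
    """HDBSCAN parameters; defaults are the AZ-level analysis values."""

    min_cluster_size: int = 100
    min_samples: int = 25

    def __post_init__(self) -> None:
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")


@dataclass
class Cluster:
    """A labelled subset of a localization table at one clustering level."""

    label: int
    members: np.ndarray           # indices into the source table
    level: str = "AZ"             # "AZ" (level 1) or "SC" (level 2)
    area_nm2: float | None = None  # filled by morphometry
    boundary: object | None = None  # shapely geometry of the alpha shape

    @property
    def n_localizations(self) -> int:
        return len(self.members)


@dataclass
class SweepResult:
    """Median AZ count per image over a (min_cluster_size x min_samples) grid."""

    mcs_values: tuple[int, ...]
    ms_values: tuple[int, ...]
    median_counts: np.ndarray     # shape (len(mcs_values), len(ms_values))
    per_table_counts: np.ndarray = field(repr=False, default=None)  # (tables, mcs, ms)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.median_counts,
                            index=pd.Index(self.mcs_values, name="min_cluster_size"),
                            columns=pd.Index(self.ms_values, name="min_samples"))


def _as_points(table) -> np.ndarray:
    if isinstance(table, LocalizationTable):
        return table.xy
    return np.asarray(table, float)


def cluster_labels(points, params: ClusteringParams) -> np.ndarray:
    """Raw HDBSCAN labels (noise = -1) for an (n, 2) point array."""
    pts = _as_points(points)
    if len(pts) < params.min_cluster_size or len(pts) <= params.min_samples:
        warnings.warn(
            f"{len(pts)} localizations < min_cluster_size {params.min_cluster_size}; "
            "no clusters", stacklevel=2)
        return np.full(len(pts), NOISE_LABEL)
    model = _SkHDBSCAN(
        min_cluster_size=params.min_cluster_size,
        min_samples=params.min_samples,
        cluster_selection_method="eom",
        copy=True,
    )
    return model.fit(pts).labels_


def cluster_localizations(table, params: ClusteringParams | None = None,
                          level: str = "AZ") -> list[Cluster]:
    """HDBSCAN clustering of localization positions.

    Every localization is assigned to exactly one cluster or to noise;
    the result is deterministic for a fixed input.  Returns clusters
    sorted by label; noise points belong to no cluster.
    """
    params = params or ClusteringParams()
    labels = cluster_labels(table, params)
    clusters = []
    for lab in np.unique(labels):
        if lab == NOISE_LABEL:
            continue
        clusters.append(Cluster(label=int(lab),
                                members=np.nonzero(labels == lab)[0],
                                level=level))
    return clusters


def parameter_sweep(tables, mcs_grid=DEFAULT_MCS_GRID,
                    ms_grid=DEFAULT_MS_GRID) -> SweepResult:
    """AZ count per image for every (min_cluster_size, min_samples) pair.

    Returns the median count over the given tables on the full grid, in
    contour-plot-ready matrix form.  Counts are of raw clusters, before
    any area filtering.
    """
    if not tables:
        raise ValueError("need at least one localization table")
    mcs_grid = tuple(int(v) for v in mcs_grid)
    ms_grid = tuple(int(v) for v in ms_grid)
    counts = np.zeros((len(tables), len(mcs_grid), len(ms_grid)), dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for t, table in enumerate(tables):
            pts = _as_points(table)
            for i, mcs in enumerate(mcs_grid):
                for j, ms in enumerate(ms_grid):
                    labels = cluster_labels(pts, ClusteringParams(mcs, ms))
                    counts[t, i, j] = len(set(labels) - {NOISE_LABEL})
    medians = np.median(counts, axis=0)
    return SweepResult(mcs_grid, ms_grid, medians, per_table_counts=counts)
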