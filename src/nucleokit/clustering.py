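"""Density-based cluster detection and per-cluster geometry.

Clusters are found with DBSCAN (radius ``eps``, minimum neighborhood size
``min_pts``, counting the point itself).  Each cluster's spatial spread is
summarized by the maximum pairwise distance over its convex-hull vertices
("diameter"); the radius is half of that and the dimensionless size
statistic is ``n = (R / 1 nm)**3``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from sklearn.cluster import DBSCAN

from .errors import FitError, ParameterError

__all__ = [
    "ClusterRecord",
    "dbscan",
    "cluster_metrics",
    "extract_clusters",
    "filter_clusters",
    "size_scaling_exponent",
]

logger = logging.getLogger(__name__)

DEFAULT_EPS_NM = 40.0
DEFAULT_MIN_PTS = 10
DEFAULT_MIN_DIAMETER_NM = 50.0


@dataclass(frozen=True)
class ClusterRecord:
    """Geometry and size of one detected cluster."""

    cluster_id: int
    member_indices: np.ndarray
    centroid_nm: tuple[float, float]
    diameter_nm: float
    R_nm: float
    localization_count: int
    n: float
    degenerate: bool = False
    cell_id: str = ""


def dbscan(points: np.ndarray, eps: float = DEFAULT_EPS_NM,
           min_pts: int = DEFAULT_MIN_PTS) -> np.ndarray:
    """Label points by density-based clustering; noise gets label -1.

    A point is a core point when at least ``min_pts`` points (itself
    included) lie within ``eps`` of it; clusters are maximal
    density-connected sets of core points plus border points, which attach
    to the first core cluster discovered in input order.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or (len(points) and points.shape[1] != 2):
        raise ParameterError("points must be an (N, 2) array")
    if len(points) and not np.all(np.isfinite(points)):
        raise ParameterError("points must be finite")
    if eps <= 0:
        raise ParameterError(f"eps must be positive, got {eps}")
    if min_pts < 1:
        raise ParameterError(f"min_pts must be >= 1, got {min_pts}")
    if len(points) == 0:
        return np.empty(0, dtype=int)
    return DBSCAN(eps=eps, min_samples=min_pts).fit(points).labels_


def cluster_metrics(points: np.ndarray, cluster_id: int = 0,
                    member_indices: np.ndarray | None = None,
                    cell_id: str = "",
                    radius_method: str = "span") -> ClusterRecord:
    """Summarize one cluster's point set.

    Diameter is the maximum pairwise distance over convex-hull vertices;
    with the default ``radius_method="span"``, ``R = diameter / 2`` and
    ``n = R**3``.  ``radius_method="mean"`` instead estimates R as
    1.5x the mean distance to the centroid (exactly ``2R/3`` in
    expectation for a uniform disc at any point count, so free of the
    finite-sample shrinkage of the max span); the diameter field still
    reports the max span for filtering.  Degenerate point sets (fewer
    than 3 points, or collinear) fall back to the max pairwise distance
    over the raw points and are flagged.
    """
    if radius_method not in ("span", "mean"):
        raise ParameterError("radius_method must be 'span' or 'mean'")
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        raise ParameterError("cannot compute metrics of an empty cluster")
    if member_indices is None:
        member_indices = np.arange(len(points))
    centroid = points.mean(axis=0)
    degenerate = False
    if len(points) >= 3:
        try:
            hull = ConvexHull(points)
            vertices = points[hull.vertices]
        except QhullError:
            degenerate = True
            vertices = points
    else:
        degenerate = True
        vertices = points
    diameter = float(pdist(vertices).max()) if len(vertices) > 1 else 0.0
    if radius_method == "mean":
        radius = 1.5 * float(np.hypot(*(points - centroid).T).mean())
    else:
        radius = diameter / 2.0
    return ClusterRecord(
        cluster_id=cluster_id,
        member_indices=np.asarray(member_indices),
        centroid_nm=(float(centroid[0]), float(centroid[1])),
        diameter_nm=diameter,
        R_nm=radius,
        localization_count=len(points),
        n=radius**3,
        degenerate=degenerate,
        cell_id=cell_id,
    )


def extract_clusters(points: np.ndarray, labels: np.ndarray,
                     cell_id: str = "",
                     radius_method: str = "span") -> list[ClusterRecord]:
    """Build a :class:`ClusterRecord` for every non-noise DBSCAN label."""
    points = np.asarray(points, dtype=float)
    records = []
    for lab in np.unique(labels):
        if lab < 0:
            continue
        idx = np.flatnonzero(labels == lab)
        records.append(cluster_metrics(points[idx], cluster_id=int(lab),
                                       member_indices=idx, cell_id=cell_id,
                                       radius_method=radius_method))
    return records


def filter_clusters(records: list[ClusterRecord],
                    min_diameter: float = DEFAULT_MIN_DIAMETER_NM) -> list[ClusterRecord]:
    """Discard clusters spanning less than ``min_diameter`` nm.

    The boundary is kept: a cluster with diameter exactly ``min_diameter``
    survives.  The number of removed records is logged.
    """
    kept = [r for r in records if r.diameter_nm >= min_diameter]
    removed = len(records) - len(kept)
    if removed:
        logger.info("filter_clusters: removed %d of %d clusters below %.0f nm",
                    removed, len(records), min_diameter)
    return kept


def size_scaling_exponent(records: list[ClusterRecord]) -> tuple[float, float]:
    """OLS slope (with sem) of log(localization count) vs log(R).

    A slope near 3 indicates volume-proportional labeling (counts ~ R^3);
    near 2, surface decoration.  Warns when the dynamic range in R is
    below 2-fold.
    """
    usable = [r for r in records if r.R_nm > 0 and r.localization_count > 0]
    if len(usable) < 10:
        raise FitError(f"need >= 10 clusters for the scaling fit, got {len(usable)}")
    r = np.array([rec.R_nm for rec in usable])
    c = np.array([rec.localization_count for rec in usable])
    if r.max() / r.min() < 2.0:
        logger.warning("size_scaling_exponent: R spans < 2-fold range; "
                       "exponent poorly constrained")
    x = np.log(r)
    y = np.log(c)
    X = np.column_stack([x, np.ones_like(x)])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - 2
    sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return float(beta[0]), float(np.sqrt(max(cov[0, 0], 0.0)))
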