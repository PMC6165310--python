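"""Per-point surface normals by local plane (PCA) fitting.

Each point's normal is the eigenvector of the smallest eigenvalue of the
covariance matrix of its k nearest neighbours,

    M = (1/k) * sum_i (p_i - pbar)(p_i - pbar)^T,

with ``pbar`` the neighbour mean.  The neighbourhood excludes the query
point itself.  By default normals are oriented to face the camera
(n . (pv - p) > 0), which the downstream visibility predicates require:
unoriented PCA normals have arbitrary sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import ParameterError
from .io_formats import PointCloud

__all__ = ["NormalParams", "estimate_normals", "knn_indices"]

logger = logging.getLogger(__name__)

_EIG_TIE_RTOL = 1e-9


@dataclass
class NormalParams:
    """k: neighbour count for the local plane fit (>= 3, < n_points)."""

    k: int = 30
    orient_to_viewpoint: bool = True

    def validate(self, n_points: int | None = None) -> None:
        if self.k < 3:
            raise ParameterError(f"k must be >= 3, got {self.k}")
        if n_points is not None and self.k >= n_points:
            raise ParameterError(
                f"k = {self.k} must be smaller than the point count {n_points}"
            )


def knn_indices(cloud: PointCloud, query, k: int) -> np.ndarray:
    """Indices of the k points nearest to ``query``, ascending by distance,
    exact ties broken toward the lower index."""
    if k < 1 or k > len(cloud):
        raise ParameterError(f"k = {k} out of range for a {len(cloud)}-point cloud")
    query = np.asarray(query, dtype=np.float64).reshape(3)
    d = np.linalg.norm(cloud.points - query, axis=1)
    order = np.lexsort((np.arange(len(d)), d))  # distance first, then index
    return order[:k]


def _neighbor_indices(points: np.ndarray, k: int) -> np.ndarray:
    """(n, k) indices of each point's k nearest neighbours, self excluded."""
    tree = cKDTree(points)
    _, idx = tree.query(points, k=k + 1, workers=-1)
    n = len(points)
    rows = np.arange(n)[:, None]
    is_self = idx == rows
    # keep k entries per row: drop the self hit when present, else the last
    has_self = is_self.any(axis=1)
    drop = np.where(has_self, is_self.argmax(axis=1), k)
    keep = np.ones_like(idx, dtype=bool)
    keep[np.arange(n), drop] = False
    return idx[keep].reshape(n, k)


def estimate_normals(cloud: PointCloud, params: NormalParams | None = None) -> PointCloud:
    """Return a copy of ``cloud`` with freshly estimated unit normals.

    Existing normals are replaced.  Degenerate neighbourhoods (eigenvalue
    ties, e.g. perfectly collinear neighbours) resolve to the eigensolver's
    deterministic eigenvector and are counted in a warning.
    """
    params = params or NormalParams()
    params.validate(len(cloud))
    pts = cloud.points
    nbr = pts[_neighbor_indices(pts, params.k)]  # (n, k, 3)
    centered = nbr - nbr.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / params.k
    evals, evecs = np.linalg.eigh(cov)  # ascending eigenvalues
    normals = evecs[:, :, 0]
    if not np.all(np.isfinite(normals)):
        raise ParameterError("normal estimation produced non-finite vectors")
    scale = np.maximum(evals[:, 2], np.finfo(float).tiny)
    ties = np.sum(np.abs(evals[:, 1] - evals[:, 0]) <= _EIG_TIE_RTOL * scale)
    if ties:
        logger.warning(
            "normal estimation: %d degenerate neighbourhoods (eigenvalue ties); "
            "deterministic eigenvector used",
            int(ties),
        )
    # eigh returns unit columns; renormalise defensively
    normals = normals / np.linalg.norm(normals, axis=1, keepdims=True)
    if params.orient_to_viewpoint:
        to_cam = cloud.viewpoint[None, :] - pts
        flip = np.einsum("ij,ij->i", normals, to_cam) < 0
        normals[flip] *= -1.0
    return PointCloud(pts.copy(), normals, cloud.viewpoint.copy())
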