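"""Reflective-symmetry plane detection and symmetry-axis computation.

The method assumes a single near-symmetric object seen from one viewpoint.
Candidate symmetry planes are anchored at the estimated fruit centroid pc
and their unit normals sample a spherical grid: for g, h = 1..u

    alpha = (g - 1) * phi_size + phi_size/2 + phi_min
    beta  = (h - 1) * theta_size + theta_size/2 + theta_min
    np    = (sin(alpha) cos(beta), sin(alpha) sin(beta), cos(alpha))

with phi in (0, pi) and theta in (-pi/2, pi/2), giving u^2 planes whose
normals cover one hemisphere (planes are undirected).

Each plane is scored by reflecting every visible point across it: points
whose mirror image would itself be invisible from the camera carry no
information and are skipped; for the rest, the score accumulates

    S = d + tau * xi

where d is the distance (cm) from the reflected point to its nearest cloud
point and xi is the angle (rad) between the reflected normal and that
neighbour's normal.  The lowest-scoring plane is the symmetry plane, and
the symmetry axis is gamma = np x (pv - pc)/||pv - pc||, normalised — the
in-plane direction perpendicular to the viewing ray.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .centroid import CentroidParams, estimate_centroid
from .config import RunConfig
from .exceptions import DegenerateGeometryError, NoSymmetryError, ParameterError
from .io_formats import PointCloud
from .normals import NormalParams, estimate_normals

__all__ = [
    "Plane",
    "PlaneGridSpec",
    "ScoreParams",
    "SymmetryResult",
    "generate_candidate_planes",
    "signed_distance",
    "reflect_point",
    "reflect_normal",
    "is_visible",
    "has_symmetric_partner",
    "score_plane",
    "select_symmetry_plane",
    "compute_axis",
    "estimate_pose",
]

logger = logging.getLogger(__name__)


@dataclass
class Plane:
    """A candidate symmetry plane: anchor point + unit normal.

    ``angles`` records the (alpha, beta, g, h) grid provenance when the
    plane came from :func:`generate_candidate_planes`.
    """

    anchor: np.ndarray
    normal: np.ndarray
    angles: Optional[Tuple[float, float, int, int]] = None

    def __post_init__(self) -> None:
        self.anchor = np.asarray(self.anchor, dtype=np.float64).reshape(3)
        self.normal = np.asarray(self.normal, dtype=np.float64).reshape(3)
        n = np.linalg.norm(self.normal)
        if abs(n - 1.0) > 1e-9:
            if n == 0:
                raise ParameterError("plane normal must be nonzero")
            self.normal = self.normal / n


@dataclass
class PlaneGridSpec:
    """Spherical grid of u^2 candidate-plane normals (u > 4)."""

    u: int = 6
    phi_range: Tuple[float, float] = (0.0, np.pi)
    theta_range: Tuple[float, float] = (-np.pi / 2, np.pi / 2)
    r: float = 1.0

    def validate(self) -> None:
        if not isinstance(self.u, (int, np.integer)) or self.u <= 4:
            raise ParameterError(f"u must be an integer > 4, got {self.u!r}")
        if not (self.phi_range[1] > self.phi_range[0]):
            raise ParameterError("phi_range must be increasing")
        if not (self.theta_range[1] > self.theta_range[0]):
            raise ParameterError("theta_range must be increasing")


@dataclass
class ScoreParams:
    """tau weights normal mismatch (radians) against distance (cm).

    ``aggregate`` turns per-point scores into a plane score.  ``mean``
    (default) averages them, so planes are compared on residual per scored
    point; ``sum`` adds them, which systematically rewards planes whose
    partner filters discard most of the cloud (a handful of
    near-self-matching rim points beat a well-aligned plane scored over the
    whole cap) and is kept only as the literal alternative.
    """

    tau: float = 3.0 * np.pi
    aggregate: str = "mean"

    def validate(self) -> None:
        if self.tau < 0:
            raise ParameterError(f"tau must be >= 0, got {self.tau}")
        if self.aggregate not in ("sum", "mean"):
            raise ParameterError(f"aggregate must be 'sum' or 'mean', got {self.aggregate!r}")


@dataclass
class SymmetryResult:
    best_plane: Plane
    best_score: float
    centroid: np.ndarray
    axis: Optional[np.ndarray] = None
    best_index: int = 0
    plane_scores: List[Tuple[Plane, float, int]] = field(default_factory=list)
    config: Optional[dict] = None

    def to_dict(self, include_plane_scores: bool = True) -> dict:
        rec = {
            "centroid": list(map(float, self.centroid)),
            "plane_normal": list(map(float, self.best_plane.normal)),
            "plane_anchor": list(map(float, self.best_plane.anchor)),
            "plane_angles": (
                None
                if self.best_plane.angles is None
                else [float(self.best_plane.angles[0]), float(self.best_plane.angles[1]),
                      int(self.best_plane.angles[2]), int(self.best_plane.angles[3])]
            ),
            "score": float(self.best_score),
            "axis": None if self.axis is None else list(map(float, self.axis)),
            "best_index": int(self.best_index),
            "config": self.config,
        }
        if include_plane_scores:
            rec["plane_scores"] = [
                {
                    "normal": list(map(float, pl.normal)),
                    "score": float(s) if np.isfinite(s) else None,
                    "n_scored": int(n),
                }
                for pl, s, n in self.plane_scores
            ]
        return rec


# ---------------------------------------------------------------------------
# geometry primitives


def generate_candidate_planes(pc, spec: PlaneGridSpec | None = None) -> List[Plane]:
    """The u^2 grid planes anchored at ``pc``, row-major in (g, h)."""
    spec = spec or PlaneGridSpec()
    spec.validate()
    pc = np.asarray(pc, dtype=np.float64).reshape(3)
    u = int(spec.u)
    phi_min, phi_max = spec.phi_range
    theta_min, theta_max = spec.theta_range
    phi_size = (phi_max - phi_min) / u
    theta_size = (theta_max - theta_min) / u
    planes: List[Plane] = []
    for g in range(1, u + 1):
        alpha = (g - 1) * phi_size + phi_size / 2 + phi_min
        for h in range(1, u + 1):
            beta = (h - 1) * theta_size + theta_size / 2 + theta_min
            n = spec.r * np.array(
                [
                    np.sin(alpha) * np.cos(beta),
                    np.sin(alpha) * np.sin(beta),
                    np.cos(alpha),
                ]
            )
            planes.append(Plane(pc, n, angles=(alpha, beta, g, h)))
    return planes


def signed_distance(point, plane: Plane) -> float:
    """(point - anchor) . normal; positive on the normal's side."""
    point = np.asarray(point, dtype=np.float64)
    return float(np.dot(point - plane.anchor, plane.normal))


def reflect_point(p, plane: Plane) -> np.ndarray:
    """Mirror ``p`` across the plane: p - 2 * np * d(p)."""
    p = np.asarray(p, dtype=np.float64)
    d = np.dot(p - plane.anchor, plane.normal)
    return p - 2.0 * np.multiply.outer(d, plane.normal)


def reflect_normal(n, plane: Plane) -> np.ndarray:
    """Mirror a direction vector across the plane's orientation (the plane
    through the origin with the same normal): n - 2 * np * (n . np)."""
    n = np.asarray(n, dtype=np.float64)
    d = np.dot(n, plane.normal)
    return n - 2.0 * np.multiply.outer(d, plane.normal)


def is_visible(p, n, pv) -> bool:
    """Point with outward normal ``n`` faces a camera at ``pv``
    (strict: n . (pv - p) > 0)."""
    p = np.asarray(p, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    pv = np.asarray(pv, dtype=np.float64)
    return bool(np.dot(n, pv - p) > 0)


def has_symmetric_partner(p, n, plane: Plane, pv) -> bool:
    """Would the mirror image of (p, n) be visible from ``pv``?

    Points failing this test sit opposite an occluded region: their
    reflection lands on the far side of the object and carries no evidence
    for or against the candidate plane.
    """
    p2 = reflect_point(p, plane)
    n2 = reflect_normal(np.asarray(n, dtype=np.float64), plane)
    return bool(np.dot(n2, np.asarray(pv, dtype=np.float64) - p2) > 0)


# ---------------------------------------------------------------------------
# scoring and selection


def _nearest_with_tie_break(tree: cKDTree, queries: np.ndarray, n_cloud: int):
    """Nearest cloud index per query, exact distance ties to the lower index."""
    k = min(2, n_cloud)
    dist, idx = tree.query(queries, k=k, workers=-1)
    if k == 1:
        return np.atleast_1d(dist), np.atleast_1d(idx)
    tie = dist[:, 0] == dist[:, 1]
    best = idx[:, 0].copy()
    best[tie] = np.minimum(idx[tie, 0], idx[tie, 1])
    return dist[:, 0], best


def _score_mask(
    points: np.ndarray,
    normals: np.ndarray,
    visible: np.ndarray,
    plane: Plane,
    pv: np.ndarray,
):
    """Reflections and the visible-with-partner mask, vectorised."""
    d = (points - plane.anchor) @ plane.normal
    refl_pts = points - 2.0 * d[:, None] * plane.normal[None, :]
    dn = normals @ plane.normal
    refl_nrm = normals - 2.0 * dn[:, None] * plane.normal[None, :]
    partner = np.einsum("ij,ij->i", refl_nrm, pv[None, :] - refl_pts) > 0
    return refl_pts, refl_nrm, visible & partner


def score_plane(
    cloud: PointCloud,
    plane: Plane,
    params: ScoreParams | None = None,
    _tree: cKDTree | None = None,
    _visible: np.ndarray | None = None,
) -> Tuple[float, int]:
    """Score one candidate plane; lower is more symmetric.

    Returns ``(score, n_scored)``.  Only points that are visible and have a
    visible symmetric partner contribute; each contributes
    ``d + tau * xi`` with d the reflected point's nearest-neighbour distance
    over the *entire* cloud and xi the unsigned angle in [0, pi] between the
    reflected normal and the neighbour's normal.  A plane with no scorable
    point gets ``inf`` (unrankable).
    """
    params = params or ScoreParams()
    params.validate()
    if not cloud.has_normals:
        raise ParameterError("score_plane requires a cloud with normals")
    pts, nrm, pv = cloud.points, cloud.normals, cloud.viewpoint
    if _visible is None:
        _visible = np.einsum("ij,ij->i", nrm, pv[None, :] - pts) > 0
    refl_pts, refl_nrm, mask = _score_mask(pts, nrm, _visible, plane, pv)
    n_scored = int(mask.sum())
    if n_scored == 0:
        return float("inf"), 0
    tree = _tree if _tree is not None else cKDTree(pts)
    dist, idx = _nearest_with_tie_break(tree, refl_pts[mask], len(pts))
    cosxi = np.einsum("ij,ij->i", refl_nrm[mask], nrm[idx])
    xi = np.arccos(np.clip(cosxi, -1.0, 1.0))
    per_point = dist + params.tau * xi
    score = per_point.sum() if params.aggregate == "sum" else per_point.mean()
    return float(score), n_scored


def select_symmetry_plane(
    cloud: PointCloud,
    planes: Sequence[Plane],
    params: ScoreParams | None = None,
) -> SymmetryResult:
    """Score every candidate plane and keep the lowest (ties to the lowest
    plane index).  The returned result carries the full score table but no
    axis yet."""
    params = params or ScoreParams()
    params.validate()
    if len(planes) == 0:
        raise ParameterError("select_symmetry_plane needs at least one plane")
    if not cloud.has_normals:
        raise ParameterError("select_symmetry_plane requires a cloud with normals")
    tree = cKDTree(cloud.points)
    visible = (
        np.einsum("ij,ij->i", cloud.normals, cloud.viewpoint[None, :] - cloud.points) > 0
    )
    table: List[Tuple[Plane, float, int]] = []
    for plane in planes:
        s, n = score_plane(cloud, plane, params, _tree=tree, _visible=visible)
        table.append((plane, s, n))
    scores = np.array([s for _, s, _ in table])
    if not np.any(np.isfinite(scores)):
        raise NoSymmetryError("every candidate plane is unrankable (no scorable points)")
    best = int(np.argmin(scores))  # argmin takes the first minimum -> lowest index
    logger.debug(
        "selected plane %d/%d, score %.4f over %d points",
        best, len(planes), scores[best], table[best][2],
    )
    pl = table[best][0]
    return SymmetryResult(
        best_plane=pl,
        best_score=float(scores[best]),
        centroid=pl.anchor.copy(),
        best_index=best,
        plane_scores=table,
    )


def compute_axis(plane: Plane, pc, pv) -> np.ndarray:
    """Symmetry axis gamma = normalise(np x (pv - pc)/||pv - pc||).

    Lies in the symmetry plane, perpendicular to the viewing ray.  The sign
    is canonicalised (largest-magnitude component positive); axes are
    compared undirected downstream.
    """
    pc = np.asarray(pc, dtype=np.float64).reshape(3)
    pv = np.asarray(pv, dtype=np.float64).reshape(3)
    v = pv - pc
    nv = np.linalg.norm(v)
    if nv == 0:
        raise DegenerateGeometryError("viewpoint coincides with the centroid")
    gamma = np.cross(plane.normal, v / nv)
    ng = np.linalg.norm(gamma)
    if ng < 1e-12:
        raise DegenerateGeometryError(
            "plane normal is parallel to the viewing ray; axis undefined"
        )
    gamma = gamma / ng
    if gamma[int(np.argmax(np.abs(gamma)))] < 0:
        gamma = -gamma
    return gamma


# ---------------------------------------------------------------------------
# pipeline


def estimate_pose(cloud: PointCloud, config: RunConfig | None = None) -> SymmetryResult:
    """Full pipeline: normals (if absent) -> centroid -> u^2 candidate
    planes -> scoring/selection -> symmetry axis.

    Deterministic for a fixed ``config.seed``.  A cloud that already carries
    normals keeps them (the estimation stage is skipped).
    """
    config = (config or RunConfig()).validate()
    if not cloud.has_normals:
        cloud = estimate_normals(cloud, NormalParams(k=config.k_normals))
    pc = estimate_centroid(
        cloud,
        CentroidParams(
            n_samples=config.centroid_samples,
            spread=config.centroid_spread,
            seed=config.seed,
            objective=config.centroid_objective,
        ),
    )
    planes = generate_candidate_planes(pc, PlaneGridSpec(u=config.u))
    result = select_symmetry_plane(
        cloud, planes, ScoreParams(tau=config.tau, aggregate=config.aggregate)
    )
    result.centroid = pc
    result.axis = compute_axis(result.best_plane, pc, cloud.viewpoint)
    result.config = config.to_dict()
    return result
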