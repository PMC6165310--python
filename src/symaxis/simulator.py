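"""Synthetic partial-view ellipsoid clouds with known ground truth.

A depth camera at the origin sees only the near face of a fruit.  The
simulator emulates this: it samples an ellipsoid surface

    (x - x0)^2 / x1^2 + (y - y0)^2 / y1^2 + (z - z0)^2 / z1^2 = 1

uniformly by area, attaches exact outward normals, and removes every point
whose normal faces away from the camera (back-face culling).  The default
benchmark sweep places a 2.5 x 2.5 x 2 cm spheroid at (3, 5, z0) cm for 45
depths z0 = 25..69 cm, mimicking a consumer depth camera's working range
with a small lateral offset.

A spheroid (x1 = y1) is rotationally symmetric about the vertical line
through its centre, so every plane containing that line is a true symmetry
plane; a triaxial ellipsoid (all half-axes distinct) has exactly the three
principal planes, which makes recovery tests unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .exceptions import DegenerateGeometryError, ParameterError
from .io_formats import PointCloud

__all__ = [
    "EllipsoidSpec",
    "sample_ellipsoid_surface",
    "cull_invisible",
    "sample_partial_view",
    "spheroid_depth_sweep",
    "DEFAULT_DEPTHS_CM",
    "DEFAULT_CENTER_XY_CM",
    "DEFAULT_HALF_AXES_CM",
    "TRIAXIAL_HALF_AXES_CM",
]

# 45 camera-to-fruit depths across the depth camera's useful range
DEFAULT_DEPTHS_CM = tuple(float(z) for z in range(25, 70))
DEFAULT_CENTER_XY_CM = (3.0, 5.0)
DEFAULT_HALF_AXES_CM = (2.5, 2.5, 2.0)
TRIAXIAL_HALF_AXES_CM = (3.0, 2.5, 2.0)


@dataclass
class EllipsoidSpec:
    """Geometry and sampling controls for one synthetic cloud."""

    center: Tuple[float, float, float]
    half_axes: Tuple[float, float, float] = DEFAULT_HALF_AXES_CM
    n_points: int = 2000
    noise_sigma: float = 0.0
    seed: int = 0
    true_axis: Tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.half_axes):
            raise ParameterError(f"half_axes must be positive, got {self.half_axes}")
        if self.n_points < 50:
            raise ParameterError(f"n_points must be >= 50, got {self.n_points}")
        if self.noise_sigma < 0:
            raise ParameterError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        ax = np.asarray(self.true_axis, dtype=np.float64)
        n = np.linalg.norm(ax)
        if n == 0:
            raise ParameterError("true_axis must be nonzero")
        self.true_axis = tuple(ax / n)

    @property
    def is_spheroid(self) -> bool:
        """Rotationally symmetric about the z line through the centre."""
        return np.isclose(self.half_axes[0], self.half_axes[1])

    def principal_plane_normals(self) -> np.ndarray:
        """Normals of the (axis-aligned) principal symmetry planes."""
        return np.eye(3)

    def to_dict(self) -> dict:
        return {
            "center": list(map(float, self.center)),
            "half_axes": list(map(float, self.half_axes)),
            "n_points": int(self.n_points),
            "noise_sigma": float(self.noise_sigma),
            "seed": int(self.seed),
            "true_axis": list(map(float, self.true_axis)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EllipsoidSpec":
        return cls(
            center=tuple(d["center"]),
            half_axes=tuple(d["half_axes"]),
            n_points=int(d.get("n_points", 2000)),
            noise_sigma=float(d.get("noise_sigma", 0.0)),
            seed=int(d.get("seed", 0)),
            true_axis=tuple(d.get("true_axis", (0.0, 0.0, 1.0))),
        )


def sample_ellipsoid_surface(
    spec: EllipsoidSpec, rng: Optional[np.random.Generator] = None
) -> PointCloud:
    """Sample ``spec.n_points`` positions uniformly by area on the ellipsoid.

    Uniform unit-sphere directions are mapped through the axis scaling and
    accepted with probability proportional to the local area distortion
    (rejection sampling), so the ellipsoid surface itself is sampled
    uniformly.  Exact outward normals are attached; no noise is added here
    (noise, when requested, is applied after the culling decision so that
    visibility is decided on clean geometry).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    a = np.asarray(spec.half_axes, dtype=np.float64)
    c = np.asarray(spec.center, dtype=np.float64)
    sigma_max = 1.0 / a.min()
    pts = np.empty((0, 3))
    while len(pts) < spec.n_points:
        draw = max(spec.n_points - len(pts), 256)
        u = rng.standard_normal((int(draw * 1.5) + 16, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        # area distortion of the map u -> a*u restricted to the sphere
        sigma = np.linalg.norm(u / a, axis=1)
        keep = rng.random(len(u)) < sigma / sigma_max
        pts = np.vstack([pts, u[keep]])
    u = pts[: spec.n_points]
    surface = c + u * a
    normals = u / a  # gradient direction of the implicit function
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return PointCloud(surface, normals)


def cull_invisible(cloud: PointCloud, pv: Sequence[float] = (0.0, 0.0, 0.0)) -> PointCloud:
    """Back-face culling: keep points whose outward normal faces a camera
    at ``pv`` (n . (pv - p) > 0).  Idempotent; errors if nothing survives."""
    if not cloud.has_normals:
        raise ParameterError("cull_invisible requires outward normals")
    pv = np.asarray(pv, dtype=np.float64).reshape(3)
    vis = np.einsum("ij,ij->i", cloud.normals, pv[None, :] - cloud.points) > 0
    if not vis.any():
        raise DegenerateGeometryError("no point is visible from the viewpoint")
    out = cloud.select(vis)
    out.viewpoint = pv
    return out


def sample_partial_view(
    spec: EllipsoidSpec, pv: Sequence[float] = (0.0, 0.0, 0.0)
) -> PointCloud:
    """Sample, cull against the camera, then (optionally) jitter positions
    with isotropic Gaussian noise of ``spec.noise_sigma`` cm."""
    rng = np.random.default_rng(spec.seed)
    cloud = sample_ellipsoid_surface(spec, rng)
    cloud = cull_invisible(cloud, pv)
    if spec.noise_sigma > 0:
        noisy = cloud.points + rng.normal(scale=spec.noise_sigma, size=cloud.points.shape)
        cloud = PointCloud(noisy, cloud.normals, cloud.viewpoint)
    return cloud


def _derived_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def spheroid_depth_sweep(
    depths: Optional[Sequence[float]] = None,
    seed: int = 0,
    n_points: int = 2000,
    noise_sigma: float = 0.0,
    center_xy: Tuple[float, float] = DEFAULT_CENTER_XY_CM,
    half_axes: Tuple[float, float, float] = DEFAULT_HALF_AXES_CM,
    pv: Sequence[float] = (0.0, 0.0, 0.0),
) -> List[Tuple[PointCloud, EllipsoidSpec]]:
    """The benchmark sweep: one culled partial-view cloud per depth.

    Defaults reproduce the 45-cloud study geometry: centres (3, 5, z0) cm
    with z0 = 25..69 cm step 1, half-axes (2.5, 2.5, 2) cm, camera at the
    origin.  Each cloud's RNG seed is derived deterministically from
    ``seed`` and the depth index.
    """
    if depths is None:
        depths = DEFAULT_DEPTHS_CM
    out: List[Tuple[PointCloud, EllipsoidSpec]] = []
    for i, z0 in enumerate(depths):
        spec = EllipsoidSpec(
            center=(center_xy[0], center_xy[1], float(z0)),
            half_axes=half_axes,
            n_points=n_points,
            noise_sigma=noise_sigma,
            seed=_derived_seed(seed, i),
        )
        out.append((sample_partial_view(spec, pv), spec))
    return out
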