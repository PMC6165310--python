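"""Fruit-centroid estimation from a one-sided partial cloud.

A depth camera sees only the near face of the fruit, so the coordinate mean
of the visible points sits well in front of the true centre.  The estimator
instead draws random candidate points around the cloud and keeps the one
whose distances to all cloud points best satisfy a "centre-like" objective:

``distance_std`` (default)
    standard deviation of the point distances — zero at the centre of a
    sphere, small at the centre of a near-spherical fruit, even when only a
    cap of the surface is visible.
``rms_distance``
    root-mean-square distance sqrt((1/m) * sum ||pr - pi||^2).  Its true
    minimiser is the coordinate mean of the visible cap, so it does not
    recover the centre of a one-sided cloud; it is kept as the literal
    alternative objective.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .exceptions import ParameterError
from .io_formats import PointCloud

__all__ = ["CentroidParams", "estimate_centroid"]

_CHUNK = 512  # candidates per distance-matrix block, caps memory


@dataclass
class CentroidParams:
    n_samples: int = 2000
    spread: Union[str, float, tuple] = "auto"
    seed: int = 0
    objective: str = "distance_std"

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ParameterError(f"n_samples must be >= 1, got {self.n_samples}")
        if self.objective not in ("distance_std", "rms_distance"):
            raise ParameterError(
                f"objective must be 'distance_std' or 'rms_distance', got {self.objective!r}"
            )
        if not isinstance(self.spread, str):
            spread = np.atleast_1d(np.asarray(self.spread, dtype=np.float64))
            if np.any(spread <= 0):
                raise ParameterError("spread must be positive")
        elif self.spread != "auto":
            raise ParameterError(f"spread must be 'auto' or positive, got {self.spread!r}")


def _objective(candidates: np.ndarray, points: np.ndarray, kind: str) -> np.ndarray:
    vals = np.empty(len(candidates))
    for lo in range(0, len(candidates), _CHUNK):
        block = candidates[lo : lo + _CHUNK]
        d = np.linalg.norm(block[:, None, :] - points[None, :, :], axis=2)
        if kind == "rms_distance":
            vals[lo : lo + len(block)] = np.sqrt(np.mean(d * d, axis=1))
        else:
            vals[lo : lo + len(block)] = d.std(axis=1)
    return vals


def estimate_centroid(cloud: PointCloud, params: CentroidParams | None = None) -> np.ndarray:
    """Randomised search for the fruit centre.

    Candidates are drawn from an axis-aligned normal distribution centred at
    the cloud's coordinate mean.  ``spread='auto'`` uses the per-axis extent
    of the cloud's bounding box as the standard deviation, which places
    candidates both in front of and behind the visible cap.  Deterministic
    for a fixed seed; the returned point minimises the objective over the
    drawn candidates (ties to the first drawn).
    """
    params = params or CentroidParams()
    params.validate()
    pts = cloud.points
    center = pts.mean(axis=0)
    if isinstance(params.spread, str):  # auto
        spread = pts.max(axis=0) - pts.min(axis=0)
        spread = np.where(spread > 0, spread, max(spread.max(), 1.0))
    else:
        spread = np.broadcast_to(
            np.atleast_1d(np.asarray(params.spread, dtype=np.float64)), (3,)
        )
    rng = np.random.default_rng(params.seed)
    candidates = center + rng.standard_normal((params.n_samples, 3)) * spread
    vals = _objective(candidates, pts, params.objective)
    return candidates[int(np.argmin(vals))].copy()
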