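"""Run configuration: defaults, YAML files, and flag overrides.

Precedence is flags > config file > defaults.  Defaults follow the method's
published operating point where one exists (u = 6 candidate-plane grid,
tau = 3*pi score weight); the rest are documented package choices.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional

import yaml

from .exceptions import ParameterError

__all__ = ["RunConfig", "parse_config"]


@dataclass
class RunConfig:
    u: int = 6                      # candidate planes per angle -> u^2 planes
    tau: float = 3.0 * math.pi      # weight of normal mismatch (rad) vs distance (cm)
    k_normals: int = 30             # neighbours for the local plane fit
    centroid_objective: str = "distance_std"
    centroid_samples: int = 2000
    centroid_spread: object = "auto"  # cm, or "auto" = bounding-box extent
    seed: int = 0
    scale: float = 1.0              # multiplicative unit conversion on read
    n_points: int = 2000            # simulator surface samples before culling
    noise_sigma: float = 0.0        # simulator point noise, cm
    aggregate: str = "mean"         # per-plane score aggregation: mean | sum

    def validate(self) -> "RunConfig":
        if not isinstance(self.u, int) or self.u <= 4:
            raise ParameterError(f"u must be an integer > 4, got {self.u!r}")
        if self.tau < 0:
            raise ParameterError(f"tau must be >= 0, got {self.tau}")
        if self.k_normals < 3:
            raise ParameterError(f"k_normals must be >= 3, got {self.k_normals}")
        if self.centroid_samples < 1:
            raise ParameterError(
                f"centroid_samples must be >= 1, got {self.centroid_samples}"
            )
        if self.centroid_objective not in ("distance_std", "rms_distance"):
            raise ParameterError(
                f"centroid_objective must be 'distance_std' or 'rms_distance', "
                f"got {self.centroid_objective!r}"
            )
        if self.aggregate not in ("sum", "mean"):
            raise ParameterError(f"aggregate must be 'sum' or 'mean', got {self.aggregate!r}")
        if self.scale <= 0:
            raise ParameterError(f"scale must be positive, got {self.scale}")
        if self.n_points < 50:
            raise ParameterError(f"n_points must be >= 50, got {self.n_points}")
        if self.noise_sigma < 0:
            raise ParameterError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw).validate()


_VALID_KEYS = {f.name for f in dataclasses.fields(RunConfig)}


def parse_config(path: Optional[str] = None, **overrides) -> RunConfig:
    """Build a validated :class:`RunConfig`.

    ``path`` names an optional YAML file whose keys mirror the dataclass
    fields.  Keyword overrides (typically CLI flags) win over file values;
    overrides passed as ``None`` are ignored so that unset flags fall
    through to the file or the defaults.
    """
    values: dict = {}
    if path is not None:
        try:
            with open(path, "r", encoding="utf-8") as fh:
                loaded = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise ParameterError(f"cannot read config file {path}: {exc}") from exc
        except yaml.YAMLError as exc:
            raise ParameterError(f"malformed YAML in {path}: {exc}") from exc
        if not isinstance(loaded, dict):
            raise ParameterError(f"config file {path} must contain a mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(values) - _VALID_KEYS
    if unknown:
        raise ParameterError(
            f"unknown config keys {sorted(unknown)}; valid keys: {sorted(_VALID_KEYS)}"
        )
    return RunConfig(**values).validate()
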