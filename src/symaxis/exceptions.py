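"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: parameter errors -> 2, I/O errors -> 3,
degenerate-geometry errors -> 4.
"""


class SymaxisError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SymaxisError, ValueError):
    """A tunable parameter violates its contract (e.g. u <= 4, k >= n)."""


class CloudIOError(SymaxisError, OSError):
    """A point-cloud or result file could not be read or written."""


class CloudParseError(CloudIOError):
    """A file was readable but malformed; the message names the offending
    line or element."""


class EmptyCloudError(CloudIOError):
    """A file parsed cleanly but contains zero points."""


class DegenerateGeometryError(SymaxisError):
    """Geometry collapsed: culling removed every point, or the symmetry-plane
    normal is parallel to the viewing ray so the axis cross product vanishes."""


class NoSymmetryError(DegenerateGeometryError):
    """Every candidate plane was unrankable (no point survived the
    symmetric-partner filters for any plane)."""
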