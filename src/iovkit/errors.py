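"""Exception types shared across the package."""


class IOVError(Exception):
    """Base class for all package errors."""


class ContourParseError(IOVError):
    """A contour file is malformed (names the offending ROI/slice)."""


class CoordinateError(IOVError):
    """A coordinate does not fit the declared grid (z off-slice, out of extent)."""


class GridMismatchError(IOVError):
    """Two volumes do not share an identical grid."""


class UndefinedMetricError(IOVError):
    """The requested statistic is undefined for the given inputs."""


class ConfigError(IOVError):
    """A run configuration value is invalid or unresolvable."""
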