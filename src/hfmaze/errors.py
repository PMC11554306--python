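"""Exception types shared across the package."""


class HFMazeError(Exception):
    """Base class for all package-specific errors."""


class PackingInfeasibleError(HFMazeError):
    """Rejection sampling could not place the requested holes under the spacing constraints."""


class InvalidRotationError(HFMazeError):
    """Rotation angle is not a multiple of 90 degrees."""


class OutOfArenaError(HFMazeError):
    """A point lies outside the arena disc."""


class NoQualifyingHoleError(HFMazeError):
    """No hole satisfies the target-selection constraints."""


class TrajectoryFormatError(HFMazeError):
    """Malformed trajectory file (header, monotonicity, gaps)."""


class GapTooLongError(TrajectoryFormatError):
    """A gap in the time base exceeds the interpolation limit."""


class DegenerateGeometryError(HFMazeError):
    """Start and target coincide (or another degenerate configuration)."""


class InsufficientPathError(HFMazeError):
    """Trajectory contains no point pair at the required separation."""


class ConfigError(HFMazeError):
    """Invalid or unknown configuration values."""
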