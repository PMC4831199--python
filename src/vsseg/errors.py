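"""Exception hierarchy for vsseg."""


class VssegError(Exception):
    """Base class for all vsseg errors."""


class InvalidParameterError(VssegError, ValueError):
    """A parameter is outside its admissible range."""


class GeometryError(VssegError, ValueError):
    """Two grids that must share a geometry do not."""


class UnusableSeedsError(VssegError, ValueError):
    """The seed label map cannot drive a segmentation (e.g. no foreground)."""


class StrokePlacementError(VssegError, RuntimeError):
    """A random stroke could not be placed inside the requested region."""


class InvalidSpecError(VssegError, ValueError):
    """A phantom specification is geometrically degenerate."""


class FormatError(VssegError, ValueError):
    """A volume file cannot be read or has unsupported structure."""


class NumericalFailureError(VssegError, RuntimeError):
    """The level-set update produced non-finite values."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration


class UndefinedMetricError(VssegError, ValueError):
    """A score is undefined for the given masks (e.g. both empty)."""
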