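"""Exception hierarchy shared across the toolkit.

Every error raised by nptraj derives from :class:`NptrajError` so pipeline
drivers can distinguish data problems from programming errors.
"""


class NptrajError(Exception):
    """Base class for all nptraj errors."""


class ConfigError(NptrajError):
    """Invalid configuration or parameter value."""


class EmptyInputError(NptrajError):
    """An input file or dataset contained no usable records."""


class MalformedTrajectoryError(NptrajError):
    """Trajectory frames are inconsistent with each other or the topology."""


class ParseError(NptrajError):
    """A text input could not be parsed; message names the offending line."""


class SelectionError(NptrajError):
    """A selection resolved to an empty or otherwise unusable atom set."""


class DegenerateFitError(NptrajError):
    """Superposition attempted on fewer than three non-collinear atoms."""


class InsufficientFramesError(NptrajError):
    """An analysis requiring multiple frames received too few."""


class TopologyError(NptrajError):
    """Chemically inconsistent topology (e.g. a hydrogen with no donor)."""


class ConvergenceError(NptrajError):
    """Iterative solver failed to converge within its iteration budget."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class DisconnectedDatasetError(NptrajError):
    """Umbrella windows form clusters with no histogram overlap."""


class NoPlateauError(NptrajError):
    """PMF has no flat large-distance region to reference a binding energy."""


class UndefinedDetachmentError(NptrajError):
    """Force profile carries no positive signal to locate detachment."""


class StabilityError(NptrajError):
    """A stochastic integrator left its domain; reduce the timestep."""
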