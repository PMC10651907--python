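"""Exception hierarchy for the activegaze pipeline."""


class ActiveGazeError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(ActiveGazeError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(ActiveGazeError, ValueError):
    """A stream / trial file does not conform to its schema."""


class SynchronizationError(ActiveGazeError):
    """Head and gaze streams have no usable temporal overlap."""


class GenerationError(ActiveGazeError):
    """Random stimulus / itinerary generation exhausted its retry budget."""


class MissingDesignError(ActiveGazeError):
    """A repeated-measures design has empty subject x level cells."""


class DegenerateDesignError(ActiveGazeError):
    """A repeated-measures design has no residual variance."""
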