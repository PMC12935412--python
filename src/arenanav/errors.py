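"""Package exception hierarchy."""


class ArenaNavError(Exception):
    """Base class for all arenanav errors."""


class InvalidScheduleError(ArenaNavError):
    """Object-collection schedule does not cover every object the required
    number of times."""


class SimulationError(ArenaNavError):
    """A simulated walk failed to terminate within the step cap."""


class InsufficientDataError(ArenaNavError):
    """Too few samples/observations for the requested metric."""


class SessionValidationError(ArenaNavError):
    """Session files violate the structural schema (strict mode)."""


class FitError(ArenaNavError):
    """A statistical model could not be fit (rank deficiency, separation,
    non-convergence)."""
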