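"""Exception hierarchy for sprintavp."""


class SprintAVPError(Exception):
    """Base class for all sprintavp errors."""


class InputError(SprintAVPError, ValueError):
    """Invalid or non-finite input values."""


class InsufficientDataError(InputError):
    """Too few samples/points to perform the requested operation."""


class ConvergenceError(SprintAVPError, RuntimeError):
    """Nonlinear fit failed to converge after all restarts."""


class NonPhysicalProfileError(SprintAVPError, ValueError):
    """A fitted line implies a non-physical sprint profile (e.g. non-negative
    slope or non-positive intercept in acceleration-velocity space)."""


class NumericalDomainError(SprintAVPError, ValueError):
    """A quantity left its mathematically valid domain during computation."""
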