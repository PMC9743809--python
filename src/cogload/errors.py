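"""Exception hierarchy shared across the package."""


class CogloadError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(CogloadError, ValueError):
    """An argument violates a documented precondition."""


class ConfigurationError(CogloadError, ValueError):
    """A configuration value is inconsistent or missing."""


class GenerationError(CogloadError, RuntimeError):
    """A requested synthetic object cannot be constructed."""


class AlignmentError(CogloadError, ValueError):
    """Trials and response key (or streams) do not line up."""


class InsufficientDataError(CogloadError, ValueError):
    """Too few samples to compute the requested quantity."""


class UndefinedBaselineError(CogloadError, ZeroDivisionError):
    """Reference power is non-positive; ERD/ERS is undefined."""


class DegenerateInputError(CogloadError, ValueError):
    """Input has no variation; the statistic is undefined."""


class TimelineError(CogloadError, ValueError):
    """Simulated intervals overlap or leave the session span."""


class FormatError(CogloadError, ValueError):
    """A file does not match the documented dialect."""


class IntegrityError(CogloadError, ValueError):
    """Cross-checked fields within a file disagree."""
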