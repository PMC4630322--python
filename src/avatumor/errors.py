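"""Exception types shared across the package."""


class AvatumorError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(AvatumorError, ValueError):
    """A parameter violates its documented domain."""


class SingularInputError(AvatumorError, ValueError):
    """An input makes the requested expression singular."""


class NoRootError(AvatumorError, ValueError):
    """A root-finding target lies outside the attainable range."""


class ConfigurationError(AvatumorError, ValueError):
    """A configuration value combination is unusable."""


class OutOfDomainError(AvatumorError, ValueError):
    """A position or cell lies outside the simulation domain."""


class StepSizeError(AvatumorError, ValueError):
    """An explicit time step violates the scheme's stability contract."""


class InvalidStateError(AvatumorError, ValueError):
    """A state variable is outside its admissible range."""


class DegenerateFitError(AvatumorError, ValueError):
    """The data cannot constrain the requested fit (e.g. constant series)."""


class FitError(AvatumorError, RuntimeError):
    """A nonlinear fit failed to converge; carries the initialization used."""

    def __init__(self, message: str, init: dict | None = None):
        super().__init__(message)
        self.init = dict(init or {})
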