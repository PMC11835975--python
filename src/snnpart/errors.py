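"""Exception hierarchy shared across the package."""


class SnnPartError(Exception):
    """Base class for all package-specific errors."""


class CapacityError(SnnPartError):
    """A requested resource exceeds what the substrate provides."""


class ConfigurationError(SnnPartError):
    """A network / experiment description is incomplete or inconsistent."""


class SchedulingError(SnnPartError):
    """The execution-instance graph cannot be ordered sequentially."""


class ValidationError(SnnPartError):
    """Numerical inputs violate a precondition (non-finite weights, bad labels, ...)."""


class UndefinedScaleError(SnnPartError):
    """The hardware-to-software trace scale factor is not identifiable."""
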