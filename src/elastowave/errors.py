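"""Exception hierarchy.

All package errors derive from :class:`ElastowaveError` so callers can catch
one base class; the CLI maps validation errors to exit code 2 and numerical
failures to exit code 3.
"""


class ElastowaveError(Exception):
    """Base class for all package errors."""


class ParameterDomainError(ElastowaveError, ValueError):
    """A parameter violates its physical domain (e.g. negative modulus)."""


class InstabilityError(ElastowaveError, ArithmeticError):
    """A wave-speed squared became non-positive (excessive compressive
    prestress); the model does not treat buckling."""


class ResolutionError(ElastowaveError, ValueError):
    """A field is too poorly sampled or too noisy for phase-gradient
    speed estimation."""


class IdentifiabilityError(ElastowaveError, ValueError):
    """The requested fit is under-determined (fewer distinct frequencies
    than free parameters)."""


class SchemaError(ElastowaveError, ValueError):
    """A serialized table violates the expected schema."""


class ConfigError(ElastowaveError, ValueError):
    """A configuration file failed validation."""
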