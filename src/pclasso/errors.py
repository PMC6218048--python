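"""Exception hierarchy used across the package."""


class PCLassoError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PCLassoError):
    """Invalid configuration of a generator, template or run."""


class ValidationError(PCLassoError):
    """Input data violate a documented precondition."""


class ShapeError(ValidationError):
    """Array dimensions are inconsistent with each other or a template."""


class FormatError(PCLassoError):
    """A file could not be parsed as the expected format."""


class ComputationError(PCLassoError):
    """A numerical step produced an unusable result (e.g. zero reference mean)."""


class FitError(PCLassoError):
    """An iterative fit failed to converge; carries diagnostics in args."""


class DegenerateInputError(ValidationError):
    """Input is degenerate for the requested operation (e.g. zero variance)."""
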