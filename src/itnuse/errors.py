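"""Exception hierarchy.

Every error raised deliberately by this package derives from :class:`ItnUseError`,
so callers (and the CLI, which maps subclasses to exit codes) can distinguish
pipeline failures from programming errors.
"""


class ItnUseError(Exception):
    """Base class for all errors raised by itnuse."""


class ConfigurationError(ItnUseError, ValueError):
    """A configuration value is missing, malformed, or out of range."""


class SchemaError(ItnUseError, ValueError):
    """An input table does not follow the documented column conventions."""


class TableValidationError(ItnUseError, ValueError):
    """Table contents violate a record-level invariant (e.g. a used net with reasons)."""


class CodebookError(ItnUseError, ValueError):
    """A reason codebook is internally inconsistent."""


class HarmonizationError(ItnUseError, ValueError):
    """Strict harmonization met a raw reason code absent from the codebook."""


class EstimationError(ItnUseError, ValueError):
    """An estimate was requested on an empty or degenerate domain."""


class DependencyError(ItnUseError, RuntimeError):
    """A pipeline stage was invoked before the stage that produces its inputs."""
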