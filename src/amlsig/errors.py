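"""Exception hierarchy.

User-facing errors (bad files, bad parameters) derive from :class:`UserInputError`
so the CLI can map them to exit code 1; anything else is an internal error (2).
"""


class AmlsigError(Exception):
    """Base class for all errors raised by this package."""


class UserInputError(AmlsigError):
    """Problems attributable to user-supplied files or parameters."""


class FormatError(UserInputError):
    """A file does not conform to its declared format."""


class SchemaError(UserInputError):
    """A tabular file is missing required columns."""


class ValidationError(UserInputError):
    """Values violate a domain invariant (non-finite, out of range, duplicated)."""


class ConfigurationError(UserInputError):
    """A simulation or pipeline configuration violates its invariants."""


class PipelineError(AmlsigError):
    """A pipeline stage cannot proceed (empty intersections, missing samples...)."""
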