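"""Exception hierarchy shared across the package.

All errors derive from :class:`TraitFilterError` so callers can catch a
single base class; the CLI maps them to nonzero exit codes with the
offending field or view named in the message.
"""


class TraitFilterError(Exception):
    """Base class for all package errors."""


class ConfigError(TraitFilterError, ValueError):
    """A generator or pipeline configuration field is invalid."""


class SchemaError(TraitFilterError, ValueError):
    """A specimen table does not conform to the required schema."""


class InputError(TraitFilterError, ValueError):
    """An operation received an argument outside its domain."""


class MeasurementError(TraitFilterError, ValueError):
    """An image measurement could not be taken (e.g. empty mask)."""


class UndefinedSESError(TraitFilterError, ZeroDivisionError):
    """The SES denominator for the requested mode is zero."""
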