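"""Exception hierarchy.

Every reader and analysis stage raises a subclass of :class:`BandscapeError`
so callers can distinguish pipeline failures from programming errors.
"""


class BandscapeError(Exception):
    """Base class for all package errors."""


class ParseError(BandscapeError):
    """A file violated its declared schema (bad cell, missing column, ...)."""


class ValidationError(BandscapeError):
    """An in-memory table violated a type invariant."""


class AmbiguityError(BandscapeError):
    """An identifier mapping was not one-to-one."""


class ConfigError(BandscapeError):
    """A simulation or analysis configuration value is out of range."""


class DegenerateDataError(BandscapeError):
    """Input data cannot support the requested statistic (empty group,
    zero variance, single stratum, ...)."""
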