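"""Exception hierarchy for connectomotif.

All errors derive from :class:`ConnectomotifError` so callers can catch the
package's failures with a single except clause; the subclasses mirror the
distinct failure contracts of the pipeline stages.
"""


class ConnectomotifError(Exception):
    """Base class for all connectomotif errors."""


class DimensionError(ConnectomotifError, ValueError):
    """A matrix is not square or does not match the expected dimension."""


class DomainError(ConnectomotifError, ValueError):
    """A value is outside its mathematical domain (negative count, p > 1, ...)."""


class ParcellationError(ConnectomotifError, ValueError):
    """Region labels disagree with the cohort's parcellation."""


class MissingDataError(ConnectomotifError, KeyError):
    """A required (subject, scan) or (subject, day) record is absent."""


class DegenerateInputError(ConnectomotifError, ValueError):
    """A statistic is undefined for this input (e.g. constant vector)."""


class ConfigError(ConnectomotifError, ValueError):
    """Inconsistent simulation or analysis configuration."""


class UsageError(ConnectomotifError, ValueError):
    """An operation was invoked with arguments outside its contract."""
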