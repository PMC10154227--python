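"""Exception hierarchy.

All package errors derive from :class:`TximbalanceError` so callers can catch
one base class; each also derives from ``ValueError`` because every failure
mode here is ultimately an invalid input or configuration.
"""


class TximbalanceError(ValueError):
    """Base class for all errors raised by tximbalance."""


class ParameterError(TximbalanceError):
    """An operation parameter is outside its valid range."""


class ConfigurationError(TximbalanceError):
    """A combination of settings is inconsistent (e.g. cohorts without replicates)."""


class FormatError(TximbalanceError):
    """An on-disk file violates its format contract."""


class DegenerateDataError(TximbalanceError):
    """Input data make the requested statistic undefined (e.g. constant values)."""


class InsufficientDataError(TximbalanceError):
    """Too few observations to run the requested operation."""
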