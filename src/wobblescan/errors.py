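"""Exception hierarchy for wobblescan.

All package errors derive from :class:`WobblescanError` so callers can catch
everything from this package with a single except clause; most also derive
from :class:`ValueError` because they signal invalid input values.
"""


class WobblescanError(Exception):
    """Base class for all wobblescan errors."""


class AlphabetError(WobblescanError, ValueError):
    """A sequence contains characters outside the expected alphabet."""


class DegenerateReferenceError(WobblescanError, ValueError):
    """The 100% fluorescence reference does not exceed the 0% reference."""


class DomainError(WobblescanError, ValueError):
    """A numeric argument is outside the domain of the statistic."""


class TraceFormatError(WobblescanError, ValueError):
    """A chromatogram file is malformed or missing required content."""


class LocalizationError(WobblescanError, ValueError):
    """The anticodon context could not be located uniquely in a trace."""


class NoSignalError(WobblescanError, ValueError):
    """No usable signal in the channels needed for an estimate."""


class SpecError(WobblescanError, ValueError):
    """A synthetic-data specification is internally inconsistent."""


class ConfigError(WobblescanError, ValueError):
    """An analysis configuration file is invalid or incomplete."""
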