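"""Exception hierarchy.

Every error raised by the package derives from :class:`DoseKitError`, so
callers can catch one type at a pipeline boundary. Subclasses also derive
from the closest builtin (``ValueError``, ``KeyError``) so the functions
behave sanely when used outside a try/except written for this package.
"""


class DoseKitError(Exception):
    """Base class for all dosekit errors."""


class ConfigurationError(DoseKitError):
    """Bad column mapping, missing mandatory column, or invalid config value."""


class EmptyInputError(DoseKitError):
    """An input table or collection was empty where data is required."""


class DomainError(DoseKitError, ValueError):
    """A physical quantity is outside its valid domain (e.g. DLP <= 0)."""


class LabelError(DoseKitError, KeyError):
    """An organ/tissue label is not part of the weighting scheme."""


class MissingStratumError(DoseKitError, KeyError):
    """A coefficient lookup hit a stratum absent from the table."""


class EmptyDerivationError(DoseKitError):
    """Coefficient derivation was attempted on an empty scan collection."""


class InsufficientStrataError(DoseKitError):
    """Fewer than two populated strata along the requested axis."""


class InsufficientDataError(DoseKitError):
    """Not enough observations for the requested statistic (e.g. n < 3)."""


class DegenerateInputError(DoseKitError):
    """Statistic undefined on the input (e.g. zero variance for Pearson r)."""


class MissingMappingError(DoseKitError, KeyError):
    """A legacy coefficient set does not cover the requested region/age."""
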