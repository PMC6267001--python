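"""Exception hierarchy for skinmwas.

Every stage raises a subclass of :class:`SkinMwasError`, so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class SkinMwasError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SkinMwasError):
    """Invalid simulation or pipeline configuration; message names the field."""


class ParseError(SkinMwasError):
    """Malformed input table (bad header, duplicate keys, non-numeric cells)."""


class AlignmentError(SkinMwasError):
    """Sample sets of two tables that must match do not."""


class FilterError(SkinMwasError):
    """A filtering stratum is empty or a filter cannot be applied."""


class EmptyResultError(SkinMwasError):
    """A filter removed every feature."""


class MappingError(SkinMwasError):
    """Gene-family/KO/pathway mapping is inconsistent or references unknown ids."""


class PairingError(SkinMwasError):
    """Longitudinal pairing is incomplete; message lists unpaired subjects."""


class ConstantInputError(SkinMwasError):
    """A statistic is undefined because an input vector is constant."""


class DegenerateDistanceError(SkinMwasError):
    """A dissimilarity is undefined (e.g. an all-zero abundance profile)."""


class IncompleteDesignError(SkinMwasError):
    """An association table is missing a stratum or test required by a rule."""
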