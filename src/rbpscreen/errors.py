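"""Exception hierarchy for the screening pipeline.

All package errors derive from :class:`RbpScreenError` so callers can catch
one base class at pipeline boundaries.
"""


class RbpScreenError(Exception):
    """Base class for all package-specific errors."""


class GPRFormatError(RbpScreenError):
    """A GenePix Results (ATF) file violates the expected format."""


class EmptyInputError(RbpScreenError):
    """An operation received no usable data (e.g. a scan with only controls)."""


class DegenerateBackgroundError(RbpScreenError):
    """A spot background intensity is zero or negative; the ratio is undefined."""


class DegenerateDistributionError(RbpScreenError):
    """Zero variance where a standardization or correlation requires spread."""


class InsufficientDataError(RbpScreenError):
    """Too few observations for the requested statistic."""


class ParameterError(RbpScreenError):
    """An invalid analysis parameter (non-positive threshold, inverted range...)."""


class PairingError(RbpScreenError):
    """Sense/antisense tables do not refer to the same RNA locus or thresholds."""


class ConfigError(RbpScreenError):
    """Invalid simulation or pipeline configuration."""


class UnlabeledRNAError(RbpScreenError):
    """Dye absorbance is zero: the base:dye ratio is undefined."""
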