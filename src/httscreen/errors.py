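"""Exception hierarchy for the screening pipeline."""


class HttScreenError(Exception):
    """Base class for all package errors."""


class FormatError(HttScreenError):
    """An input file is not in the expected format."""


class ValidationError(HttScreenError):
    """Input values violate a documented contract."""


class ConfigurationError(HttScreenError):
    """The run configuration is inconsistent or incomplete."""


class DegenerateDataError(HttScreenError):
    """Too few (distinct) observations to fit the requested model."""


class InsufficientDataError(HttScreenError):
    """A statistical test received fewer observations than it requires."""


class UndefinedRatioError(HttScreenError):
    """A ratio with a zero denominator was requested (e.g. DMSO mean = 0)."""
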