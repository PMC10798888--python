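"""Exception hierarchy for the methscale pipeline."""


class MethscaleError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MethscaleError, ValueError):
    """An input table does not conform to the expected layout."""


class EmptyInputError(MethscaleError, ValueError):
    """An operation received no usable data (e.g. zero overlapping samples)."""


class ConfigError(MethscaleError, ValueError):
    """A configuration or simulation parameter is out of its valid range."""


class InsufficientDataError(MethscaleError, ValueError):
    """Too few samples, species or CpGs to perform the requested computation."""


class DegenerateFitError(MethscaleError, ValueError):
    """A regression cannot be fitted (e.g. zero variance in ages)."""


class InsufficientCpGsError(MethscaleError, ValueError):
    """A pairwise comparison selected fewer CpGs than the required minimum.

    Raised by the chain walk; the threshold scan catches it and marks the
    R-squared threshold as invalid.
    """
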