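"""Exception hierarchy shared across the package."""


class NeuroageError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(NeuroageError):
    """Invalid generator or pipeline configuration; names the offending field."""


class FormatError(NeuroageError):
    """Unreadable or malformed recording file."""


class UnsupportedLayoutError(NeuroageError):
    """Recording layout the pipeline cannot process (e.g. mixed sampling rates)."""


class AllSegmentsRejectedError(NeuroageError):
    """Every segment of a recording was rejected; no spectrum can be formed."""


class DegenerateFitError(NeuroageError):
    """Calibration input has no usable variance."""


class UndefinedTestError(NeuroageError):
    """Statistical test undefined for the given data (e.g. all differences zero)."""


class DegenerateTableError(NeuroageError):
    """Contingency table with a zero marginal."""
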