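"""Exception hierarchy shared across the package."""


class TmtdError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TmtdError):
    """Invalid layout, config file, or input table schema."""


class MetricError(TmtdError):
    """A PSM-level metric cannot be computed (e.g. no bordering MS1 scan)."""


class NumericsError(TmtdError):
    """Numerical failure, e.g. a singular impurity matrix."""
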