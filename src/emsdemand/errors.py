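"""Exception hierarchy for the demand-estimation pipeline."""


class EmsDemandError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EmsDemandError):
    """Invalid generator or pipeline configuration."""


class InputError(EmsDemandError):
    """Malformed or inconsistent input data."""


class EstimationError(EmsDemandError):
    """An estimator cannot be evaluated on the given data."""


class DegenerateDistributionError(EstimationError):
    """A statistic requires variability that the data do not have."""
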