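"""Exception hierarchy shared across the package."""


class ComsnnError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ComsnnError):
    """Invalid parameter combination; the message names the violated constraint."""


class EstimationError(ComsnnError):
    """A graph statistic could not be estimated (degenerate input)."""


class CalibrationError(ComsnnError):
    """No grid point reached the calibration target within tolerance."""


class SimulationError(ComsnnError):
    """Numerical failure during network integration."""


class MetricUndefinedError(ComsnnError):
    """A metric is undefined for the given inputs (e.g. all-silent baseline)."""
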