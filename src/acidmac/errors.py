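"""Exception hierarchy shared across the package."""


class AcidmacError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(AcidmacError, ValueError):
    """A value passed to an operation violates its contract."""


class ConfigurationError(AcidmacError, ValueError):
    """A configuration file or object is invalid; message names the key."""


class FittingError(AcidmacError, RuntimeError):
    """Calibration could not be performed (e.g. singular design)."""


class SimulationError(AcidmacError, RuntimeError):
    """The simulation reached an invalid numerical state."""
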