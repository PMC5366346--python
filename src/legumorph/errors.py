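"""Exception hierarchy for legumorph."""


class LegumorphError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LegumorphError):
    """Invalid parameter set or species configuration."""


class DataValidationError(LegumorphError):
    """An input table or value violates the expected schema or range."""


class InsufficientDataError(DataValidationError):
    """Too few usable observations to attempt a fit."""


class DegenerateFitError(LegumorphError):
    """The data admit no meaningful fit (flat series, non-positive slope...)."""


class SimulationAborted(LegumorphError):
    """A simulation guard (axis count, phytomer count) was exceeded."""


class WindowError(LegumorphError):
    """A requested time window falls outside the recorded series."""
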