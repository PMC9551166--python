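"""Exception hierarchy shared across the package."""


class TriStepError(Exception):
    """Base class for all package-specific errors."""


class SpectrumParseError(TriStepError, ValueError):
    """A spectrum file contained rows that could not be parsed."""


class SpectrumFormatError(TriStepError, ValueError):
    """A spectrum file was structurally invalid (too short, missing records)."""


class ModeError(TriStepError, ValueError):
    """An operation received a spectrum in the wrong intensity mode."""


class GridError(TriStepError, ValueError):
    """Wavenumber grids are incompatible or invalid."""


class RangeError(TriStepError, ValueError):
    """A requested wavenumber range falls outside the available data."""


class DomainError(TriStepError, ValueError):
    """Input values lie outside the mathematical domain of an operation."""


class ParameterError(TriStepError, ValueError):
    """An operation received an invalid parameter value."""


class DegenerateDataError(TriStepError, ValueError):
    """Input data is degenerate for the requested operation (constant, empty class, ...)."""


class ConvergenceError(TriStepError, RuntimeError):
    """An iterative algorithm failed to converge within its iteration bound."""
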