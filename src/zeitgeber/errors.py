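"""Exception hierarchy shared across the package."""


class ZeitgeberError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(ZeitgeberError, ValueError):
    """A kinetic or protocol parameter is outside its admissible domain."""


class SimulationError(ZeitgeberError, RuntimeError):
    """The ODE integrator failed; carries the dilution cycle index."""

    def __init__(self, message: str, cycle: int | None = None):
        super().__init__(message)
        self.cycle = cycle


class EstimationError(ZeitgeberError, RuntimeError):
    """A fit or estimator did not converge or is unidentifiable."""


class CalibrationError(ZeitgeberError, ValueError):
    """Intensity calibration is degenerate (zero denominator)."""


class ClassificationError(ZeitgeberError, RuntimeError):
    """A trajectory cannot be classified (e.g. no maxima after equilibration)."""
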