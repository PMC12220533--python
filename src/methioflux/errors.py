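"""Exception hierarchy for methioflux."""


class MethioFluxError(Exception):
    """Base class for all methioflux errors."""


class UnidentifiableError(MethioFluxError):
    """A quantity cannot be determined from the given design (degenerate system)."""


class StoichiometryError(MethioFluxError):
    """A flux assignment violates steady-state mass balance on an interior pool."""


class InconsistentMeasurementError(MethioFluxError):
    """A measured value is outside the range physically allowed by the mixing model."""


class IntegrationFailureError(MethioFluxError):
    """The labeling ODE integrator returned a non-finite or failed solution."""


class TableFormatError(MethioFluxError):
    """A delimited input table is malformed; the message names file and rows."""
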