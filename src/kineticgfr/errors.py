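"""Exception hierarchy for the kinetic-GFR model."""


class KineticGfrError(Exception):
    """Base class for all package errors."""


class UnitError(KineticGfrError, ValueError):
    """An unknown or dimensionally wrong unit label was supplied."""


class DomainError(KineticGfrError, ValueError):
    """Parameters or time lie outside the model's validity region.

    Typically raised when the volume of distribution would be
    non-positive (rules B/E of the parameter constraints).
    """


class NoSteadyStateError(KineticGfrError, ArithmeticError):
    """Total clearance GFR_K + dV/dt is non-positive: no finite steady
    state exists and the concentration grows without bound."""


class UnsupportedBranchError(KineticGfrError, ValueError):
    """A derivative was requested at a removable singularity for which
    no closed-form limit branch is implemented."""


class OracleError(KineticGfrError, RuntimeError):
    """A numerical cross-check (ODE integration, finite difference)
    failed to produce a usable reference value."""
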