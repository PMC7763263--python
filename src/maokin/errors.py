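"""Exception hierarchy shared across the package."""


class MaokinError(Exception):
    """Base class for all package errors."""


class ValidationError(MaokinError, ValueError):
    """Invalid user input (negative concentration, bad grid, ...)."""


class IntegrationError(MaokinError, RuntimeError):
    """The ODE integrator failed; the message names the rate constants."""


class RangeError(MaokinError, ValueError):
    """The data do not span the feature the estimator needs
    (no 50% crossing, no descending titration region, no plateau)."""


class FitError(MaokinError, RuntimeError):
    """A nonlinear fit failed to converge; carries the initialization used."""
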