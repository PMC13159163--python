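"""Exception types raised by the phasekin library."""


class PhasekinError(Exception):
    """Base class for all phasekin-specific errors."""


class DomainError(PhasekinError, ValueError):
    """An argument lies outside the physically meaningful domain."""


class NoBarrierError(PhasekinError, ValueError):
    """Cluster work has no interior maximum (driving force is non-negative)."""


class BracketError(PhasekinError, RuntimeError):
    """A bracketed root / bisection search could not enclose its target."""


class ConvergenceError(PhasekinError, RuntimeError):
    """An iterative fit or solver failed to converge."""


class CFLViolationError(PhasekinError, RuntimeError):
    """Explicit diffusion step violates the CFL stability bound."""


class DegenerateEventError(PhasekinError, ValueError):
    """An observation carries no signal for the requested fit."""
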