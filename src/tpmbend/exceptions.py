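"""Exception hierarchy for tpmbend."""


class TPMBendError(Exception):
    """Base class for all tpmbend errors."""


class DomainError(TPMBendError, ValueError):
    """Raised when an input violates a documented precondition."""


class BeadDominatesError(DomainError):
    """The bead radius is too large relative to the measured amplitude:
    (3/2) * amplitude**2 <= bead_radius**2, so no real DNA extension exists."""


class SolverError(TPMBendError, RuntimeError):
    """A root-finder or optimiser failed; the message carries diagnostics."""


class UnattainableError(TPMBendError, ValueError):
    """The requested target value lies outside the physically reachable range."""
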