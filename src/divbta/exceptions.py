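"""Exception hierarchy shared by all divbta modules."""


class DivbtaError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(DivbtaError, ValueError):
    """Input violates a domain invariant (e.g. non-positive SD, n < 2)."""


class InsufficientDataError(DivbtaError, ValueError):
    """Too few estimates/trials for the requested fit (e.g. k < 3)."""


class DegenerateInputError(DivbtaError, ValueError):
    """Input is structurally valid but degenerate (e.g. zero sampling variance)."""


class DegenerateTrialError(DivbtaError, RuntimeError):
    """A simulated trial arm collapsed (size < 2 or zero spread) after a mechanism."""
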