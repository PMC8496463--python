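"""Exception hierarchy."""


class SpecphytoError(Exception):
    """Base class for all package errors."""


class ValidationError(SpecphytoError):
    """Raised when an input violates a documented precondition."""


class FitError(SpecphytoError):
    """Raised when a model fit fails to converge or is degenerate."""
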