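"""Exception hierarchy shared across the package."""


class MibciError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MibciError, ValueError):
    """Raised when an input violates a documented contract (ranges, schema, codes)."""


class ConvergenceError(MibciError, RuntimeError):
    """Raised when an iterative solver (e.g. the Karcher mean) fails to converge."""

    def __init__(self, message: str, last_gradient_norm: float | None = None):
        super().__init__(message)
        self.last_gradient_norm = last_gradient_norm
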