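"""Exception hierarchy shared across the package."""


class BondoscError(Exception):
    """Base class for all package errors."""


class ModelValidationError(BondoscError, ValueError):
    """A network, loop specification or model file violates its schema.

    Carries the full list of offenses so callers can report them together.
    """

    def __init__(self, messages):
        if isinstance(messages, str):
            messages = [messages]
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


class DomainError(BondoscError, ValueError):
    """A numerical input is outside the physical domain (e.g. amount <= 0)."""


class ConvergenceError(BondoscError, RuntimeError):
    """An iterative procedure failed to converge; carries diagnostics."""

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


class RootFindingError(BondoscError, RuntimeError):
    """Scalar root finding failed (no sign change or divergence)."""


class FixtureUnavailable(BondoscError, RuntimeError):
    """A model fixture requires external parameters that were not provisioned."""
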