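"""Package-specific exception types."""


class DomainError(ValueError):
    """Input outside the mathematical domain (e.g. log of a non-positive time)."""


class InsufficientEventsError(ValueError):
    """Too few uncensored events to place knots or identify a model."""


class ConvergenceError(RuntimeError):
    """Likelihood maximisation failed; carries the last gradient norm."""

    def __init__(self, message: str, grad_norm: float | None = None):
        super().__init__(message)
        self.grad_norm = grad_norm


class SchemaError(ValueError):
    """Tabular input violated the documented schema; lists itemised problems."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("schema validation failed:\n" + "\n".join(self.problems))
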