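"""Exception types shared across the package."""


class MemokinError(Exception):
    """Base class for package errors."""


class DomainError(MemokinError, ValueError):
    """An argument lies outside the physically meaningful domain."""


class InsufficientDataError(MemokinError, ValueError):
    """Too few observations to carry out the requested estimation."""


class SchemaError(MemokinError, ValueError):
    """An input table does not conform to the expected schema.

    ``errors`` collects per-row messages (with line numbers) when the
    problem is row-level rather than structural.
    """

    def __init__(self, message: str, errors: list[str] | None = None):
        self.errors = list(errors or [])
        if self.errors:
            message = message + "\n  " + "\n  ".join(self.errors)
        super().__init__(message)


class ConvergenceWarning(UserWarning):
    """A fit finished without satisfying the convergence criteria."""


class NonEquilibriumWarning(UserWarning):
    """A steady-state formula was evaluated where no steady state exists."""
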