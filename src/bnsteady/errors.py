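"""Exception hierarchy shared across the package."""


class BNSteadyError(Exception):
    """Base class for all package errors."""


class ParseError(BNSteadyError):
    """Malformed rule text (syntax error, duplicate or undefined symbol)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class StructuralError(BNSteadyError):
    """A network violates a structural invariant (e.g. undeclared variable)."""


class InputError(BNSteadyError):
    """Invalid argument to an operation (length mismatch, infeasible spec)."""


class CapExceededError(BNSteadyError):
    """A configured size cap (state-space, FVS width, solution count) was hit."""


class SolveTimeoutError(BNSteadyError):
    """The configured wall-clock limit for a solve was exceeded."""


class InternalConsistencyError(BNSteadyError):
    """A self-check failed; indicates a bug, never bad user input."""
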