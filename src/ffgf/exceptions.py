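"""Exception hierarchy shared across the package."""


class FFGFError(Exception):
    """Base class for package errors."""


class ContractError(FFGFError, ValueError):
    """A documented precondition of an operation was violated."""


class FormatError(FFGFError, ValueError):
    """An input file or array does not have the expected structure."""


class InputError(FFGFError, OSError):
    """A required input (file, directory) is missing or unreadable."""


class ConvergenceError(FFGFError, RuntimeError):
    """An iterative solver exhausted its budget before converging."""

    def __init__(self, message: str, duality_gap: float | None = None):
        super().__init__(message)
        self.duality_gap = duality_gap
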