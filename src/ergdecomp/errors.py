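"""Exception hierarchy for the ERG decomposition pipeline.

Every invariant violation raises a typed error; nothing is silently
coerced.
"""


class ErgError(Exception):
    """Base class for all package errors."""


class ValidationError(ErgError, ValueError):
    """A domain-type invariant was violated."""


class ParseError(ErgError, ValueError):
    """A trace file could not be parsed; the message names the offending line."""


class InputError(ErgError, ValueError):
    """An operation was called with inputs outside its contract."""


class FilterDesignError(ErgError, ValueError):
    """A filter specification cannot be realised (e.g. corner at/above Nyquist)."""


class ConvergenceError(ErgError, RuntimeError):
    """An optimiser failed to converge; carries best-so-far diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics
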