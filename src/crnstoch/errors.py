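"""Exception hierarchy for crnstoch."""

from __future__ import annotations


class CrnStochError(Exception):
    """Base class for all crnstoch errors."""


class ConfigurationError(CrnStochError):
    """A value assignment or run configuration is incomplete or inconsistent."""


class TableFormatError(CrnStochError):
    """A truth-table file violates the CSV contract.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class NotBooleanError(CrnStochError):
    """A polynomial is not implementable as a single truth table.

    Raised when evaluation at some {0,1} vertex is not (within tolerance)
    exactly 0 or 1.
    """


class UnknownGateError(CrnStochError, KeyError):
    """Requested gate name is not in the gate library."""


class DomainError(CrnStochError, ValueError):
    """A fractional value lies outside the unit interval."""


class UndefinedFractionError(CrnStochError, ZeroDivisionError):
    """A fraction [X1]/([X0]+[X1]) is undefined because the pair total is zero."""


class CrnFormatError(CrnStochError):
    """A plain-text reaction file violates the format contract."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CascadeError(CrnStochError):
    """Invalid stage wiring (cyclic, dangling, or ambiguous)."""


class SimulationError(CrnStochError, RuntimeError):
    """Integration failed to reach completion.

    ``state`` holds the last integrator state (species name -> concentration),
    ``context`` optional extra information such as lattice coordinates.
    """

    def __init__(self, message: str, state=None, context=None):
        self.state = state
        self.context = context
        if context:
            message = f"{message} (context: {context})"
        super().__init__(message)
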