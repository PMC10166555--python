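"""Truth tables, stochastic logic functions, and multilinear polynomials.

In stochastic logic a real value ``x`` in [0, 1] is carried by a random
bitstream whose bits are 1 with probability ``x``.  Feeding independent
streams through a combinational Boolean function ``F`` yields an output
stream whose one-probability is the *stochastic function* of ``F``: the sum,
over all minterms on which ``F`` evaluates to 1, of the product of the
per-variable probabilities.  That sum is a multilinear polynomial in the
input probabilities, and every function computable this way arises from some
truth table.

This module provides the table and polynomial containers, the closed-form
evaluation, exact (integer-coefficient) expansion of a table into its
polynomial, the vertex-evaluation inverse, the standard gate library, and
strict CSV / text-form I/O.

Row-order convention: minterm rows ascend as binary integers with the
*first* listed variable as the most significant bit.  Every other module
(CRN compilation, reaction ordering, file I/O) inherits this convention.
"""

from __future__ import annotations

import csv
import io
import itertools
import random
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import sympy

from .errors import (
    ConfigurationError,
    NotBooleanError,
    TableFormatError,
    UnknownGateError,
)

__all__ = [
    "Minterm",
    "TruthTable",
    "ProbabilityAssignment",
    "MultilinearPolynomial",
    "minterm_probability",
    "eval_stochastic_function",
    "truth_table_to_polynomial",
    "polynomial_to_truth_table",
    "gate_library",
    "GATE_NAMES",
    "random_table",
    "read_table_csv",
    "write_table_csv",
]

#: Tolerance for deciding whether a vertex value is Boolean.
BOOLEAN_TOL = 1e-9


@dataclass(frozen=True)
class Minterm:
    """One row of a truth table: a complete 0/1 assignment to all inputs."""

    bits: tuple[int, ...]
    var_names: tuple[str, ...]

    def __post_init__(self):
        if len(self.bits) != len(self.var_names):
            raise ConfigurationError("minterm bits and variable names differ in length")
        if any(b not in (0, 1) for b in self.bits):
            raise ConfigurationError(f"minterm bits must be 0/1, got {self.bits}")

    @property
    def index(self) -> int:
        """Row index: binary integer with the first variable most significant."""
        idx = 0
        for b in self.bits:
            idx = (idx << 1) | b
        return idx

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(zip(self.var_names, self.bits))


@dataclass(frozen=True)
class TruthTable:
    """An n-input Boolean function given by its 2^n output bits.

    Parameters
    ----------
    var_names :
        Ordered input variable names.  The first name is the most
        significant bit of the row index.
    outputs :
        The 2^n output bits in canonical row order.
    name :
        Name of the function / output column (default ``"F"``).
    """

    var_names: tuple[str, ...]
    outputs: tuple[int, ...]
    name: str = "F"

    def __post_init__(self):
        object.__setattr__(self, "var_names", tuple(self.var_names))
        object.__setattr__(self, "outputs", tuple(int(v) for v in self.outputs))
        if len(self.var_names) == 0:
            raise ConfigurationError("degenerate table with zero inputs")
        if len(set(self.var_names)) != len(self.var_names):
            raise ConfigurationError(f"duplicate variable names: {self.var_names}")
        if self.name in self.var_names:
            raise ConfigurationError(f"output name {self.name!r} collides with an input")
        if len(self.outputs) != 2 ** self.n:
            raise ConfigurationError(
                f"expected {2 ** self.n} outputs for {self.n} inputs, "
                f"got {len(self.outputs)}"
            )
        if any(v not in (0, 1) for v in self.outputs):
            raise ConfigurationError("table outputs must all be 0 or 1")

    @property
    def n(self) -> int:
        return len(self.var_names)

    @property
    def n_rows(self) -> int:
        return 2 ** self.n

    def minterm(self, row: int) -> Minterm:
        """The minterm (bit assignment) of a row index."""
        if not 0 <= row < self.n_rows:
            raise IndexError(f"row {row} out of range for {self.n}-input table")
        bits = tuple((row >> (self.n - 1 - i)) & 1 for i in range(self.n))
        return Minterm(bits, self.var_names)

    def minterms(self) -> Iterator[Minterm]:
        for row in range(self.n_rows):
            yield self.minterm(row)

    def ones(self) -> tuple[Minterm, ...]:
        """S1: minterms whose output is 1."""
        return tuple(m for m in self.minterms() if self.outputs[m.index] == 1)

    def zeros(self) -> tuple[Minterm, ...]:
        """S0: minterms whose output is 0."""
        return tuple(m for m in self.minterms() if self.outputs[m.index] == 0)

    def __call__(self, bits: Sequence[int]) -> int:
        return self.outputs[Minterm(tuple(bits), self.var_names).index]


@dataclass(frozen=True)
class ProbabilityAssignment:
    """Per-variable one-probabilities (equivalently, input fractions).

    ``bindings`` optionally aliases several table columns to one shared
    value: each bound column remains an independent random variable (and,
    downstream, an independent species pair) but is initialized with the
    same probability.  This supports univariate approximations computed
    with replicated inputs, where independence of the streams is required
    for the stochastic-logic closed form to hold.
    """

    values: Mapping[str, float]
    bindings: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "values", dict(self.values))
        object.__setattr__(self, "bindings", dict(self.bindings))
        for k, v in self.values.items():
            if not 0.0 <= float(v) <= 1.0:
                raise ConfigurationError(f"probability {k}={v} outside [0, 1]")

    def __getitem__(self, var: str) -> float:
        key = self.bindings.get(var, var)
        try:
            return float(self.values[key])
        except KeyError:
            raise ConfigurationError(f"no probability assigned to variable {var!r}") from None

    def covers(self, var_names: Iterable[str]) -> bool:
        return all(self.bindings.get(v, v) in self.values for v in var_names)


def _as_assignment(assignment) -> ProbabilityAssignment:
    if isinstance(assignment, ProbabilityAssignment):
        return assignment
    return ProbabilityAssignment(assignment)


def minterm_probability(assignment, m: Minterm) -> float:
    """Probability of a minterm: prod_i c_{i, v_i}.

    ``c_{i,1} = x_i`` and ``c_{i,0} = 1 - x_i`` where ``x_i`` is the
    one-probability of variable ``i``.
    """
    assignment = _as_assignment(assignment)
    p = 1.0
    for var, bit in m:
        x = assignment[var]
        p *= x if bit == 1 else 1.0 - x
    return p


def eval_stochastic_function(tt: TruthTable, assignment) -> float:
    """Closed-form output probability: the sum of S1 minterm probabilities."""
    assignment = _as_assignment(assignment)
    return sum(minterm_probability(assignment, m) for m in tt.ones())


# ---------------------------------------------------------------------------
# Multilinear polynomials
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MultilinearPolynomial:
    """A polynomial with no variable raised above power 1.

    ``coeffs`` maps a frozenset of variable names (the monomial's support;
    the empty set is the constant term) to its coefficient.  Coefficients
    derived from truth tables are exact integers.
    """

    coeffs: Mapping[frozenset, float]
    var_names: tuple[str, ...] = ()

    def __post_init__(self):
        coeffs = {frozenset(s): c for s, c in self.coeffs.items() if c != 0}
        object.__setattr__(self, "coeffs", coeffs)
        support = set().union(*coeffs.keys()) if coeffs else set()
        if self.var_names:
            names = tuple(self.var_names)
            if not support <= set(names):
                raise ConfigurationError(
                    f"coefficient variables {sorted(support - set(names))} "
                    "not in declared var_names"
                )
        else:
            names = tuple(sorted(support))
        object.__setattr__(self, "var_names", names)

    def evaluate(self, assignment) -> float:
        assignment = _as_assignment(assignment)
        total = 0.0
        for subset, coef in self.coeffs.items():
            term = float(coef)
            for var in subset:
                term *= assignment[var]
            total += term
        return total

    def __call__(self, assignment) -> float:
        return self.evaluate(assignment)

    def coefficient(self, *vars: str) -> float:
        return self.coeffs.get(frozenset(vars), 0)

    @property
    def constant(self) -> float:
        return self.coeffs.get(frozenset(), 0)

    # -- text form ----------------------------------------------------------

    def to_text(self) -> str:
        """Render in ``"1 - a - b + a*b"`` style with deterministic term order."""
        order = {v: i for i, v in enumerate(self.var_names)}
        keys = sorted(self.coeffs, key=lambda s: (len(s), sorted(order[v] for v in s)))
        if not keys:
            return "0"
        parts = []
        for subset in keys:
            coef = self.coeffs[subset]
            mag = abs(coef)
            mono = "*".join(sorted(subset, key=order.get))
            if not subset:
                body = _fmt_num(mag)
            elif mag == 1:
                body = mono
            else:
                body = f"{_fmt_num(mag)}*{mono}"
            sign = "-" if coef < 0 else "+"
            parts.append((sign, body))
        first_sign, first_body = parts[0]
        text = ("-" if first_sign == "-" else "") + first_body
        for sign, body in parts[1:]:
            text += f" {sign} {body}"
        return text

    @classmethod
    def from_text(cls, text: str, var_names: Sequence[str] | None = None
                  ) -> "MultilinearPolynomial":
        """Parse ``"1 - a - b + a*b"`` style text (sympy syntax accepted)."""
        try:
            expr = sympy.sympify(text, rational=True)
        except (sympy.SympifyError, SyntaxError, TypeError) as exc:
            raise ConfigurationError(f"cannot parse polynomial {text!r}: {exc}") from exc
        expr = sympy.expand(expr)
        symbols = sorted(expr.free_symbols, key=lambda s: s.name)
        poly = sympy.Poly(expr, *symbols) if symbols else None
        coeffs: dict[frozenset, float] = {}
        if poly is None:
            coeffs[frozenset()] = _num(expr)
        else:
            for powers, coef in poly.terms():
                if any(p > 1 for p in powers):
                    raise ConfigurationError(f"polynomial {text!r} is not multilinear")
                subset = frozenset(s.name for s, p in zip(symbols, powers) if p == 1)
                coeffs[subset] = _num(coef)
        return cls(coeffs, tuple(var_names) if var_names else ())


def _num(x) -> float:
    """Sympy number -> int where exact, float otherwise."""
    if getattr(x, "is_Integer", False):
        return int(x)
    f = float(x)
    return int(f) if f == int(f) else f


def _fmt_num(x) -> str:
    return str(int(x)) if float(x) == int(x) else repr(float(x))


def truth_table_to_polynomial(tt: TruthTable) -> MultilinearPolynomial:
    """Expand the sum of S1 minterm probabilities into multilinear form.

    Each minterm contributes ``prod_{v_i=1} x_i * prod_{v_i=0} (1 - x_i)``;
    expanding the (1 - x) factors yields exact integer coefficients.
    """
    coeffs: dict[frozenset, int] = {}
    for m in tt.ones():
        ones = tuple(v for v, b in m if b == 1)
        zeros = tuple(v for v, b in m if b == 0)
        for r in range(len(zeros) + 1):
            for extra in itertools.combinations(zeros, r):
                key = frozenset(ones + extra)
                coeffs[key] = coeffs.get(key, 0) + (-1) ** r
    return MultilinearPolynomial(coeffs, tt.var_names)


def polynomial_to_truth_table(p: MultilinearPolynomial, name: str = "F") -> TruthTable:
    """Evaluate ``p`` on all {0,1} vertices and return the table of values.

    Raises
    ------
    NotBooleanError
        If some vertex value differs from 0 or 1 by more than 1e-9, the
        polynomial is not the stochastic function of any single table.
    """
    var_names = p.var_names
    if not var_names:
        raise NotBooleanError(
            f"constant polynomial {p.constant} has no input variables; "
            "not implementable as a single truth table"
        )
    outputs = []
    for bits in itertools.product((0, 1), repeat=len(var_names)):
        val = p.evaluate(dict(zip(var_names, bits)))
        rounded = round(val)
        if rounded not in (0, 1) or abs(val - rounded) > BOOLEAN_TOL:
            raise NotBooleanError(
                f"vertex {dict(zip(var_names, bits))} evaluates to {val}, "
                "not 0 or 1: not implementable as a single truth table"
            )
        outputs.append(rounded)
    return TruthTable(var_names, tuple(outputs), name=name)


# ---------------------------------------------------------------------------
# Gate library
# ---------------------------------------------------------------------------

_GATES: dict[str, tuple[tuple[str, ...], tuple[int, ...], str]] = {
    "NOT": (("a",), (1, 0), "b"),
    "AND": (("a", "b"), (0, 0, 0, 1), "c"),
    "OR": (("a", "b"), (0, 1, 1, 1), "c"),
    "NAND": (("a", "b"), (1, 1, 1, 0), "c"),
    "NOR": (("a", "b"), (1, 0, 0, 0), "c"),
    "XOR": (("a", "b"), (0, 1, 1, 0), "c"),
    "XNOR": (("a", "b"), (1, 0, 0, 1), "c"),
}

GATE_NAMES = tuple(_GATES)


def gate_library(name: str) -> TruthTable:
    """Standard table for a basic gate (NOT, AND, OR, NAND, NOR, XOR, XNOR)."""
    try:
        var_names, outputs, out = _GATES[name.upper()]
    except KeyError:
        raise UnknownGateError(
            f"unknown gate {name!r}; available: {', '.join(GATE_NAMES)}"
        ) from None
    return TruthTable(var_names, outputs, name=out)


def random_table(n: int, seed: int, name: str = "F") -> TruthTable:
    """A uniformly random n-input table, reproducible per seed."""
    if not 1 <= n <= 8:
        raise ConfigurationError(f"random tables support 1 <= n <= 8, got {n}")
    rng = random.Random(seed)
    var_names = tuple(f"x{i + 1}" for i in range(n))
    outputs = tuple(rng.randint(0, 1) for _ in range(2 ** n))
    return TruthTable(var_names, outputs, name=name)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------
#
# Contract: header row = variable names then function name; 2^n data rows of
# 0/1 in canonical row order (input bit columns included and checked).


def write_table_csv(tt: TruthTable, path_or_file) -> None:
    def _write(fh):
        w = csv.writer(fh)
        w.writerow(list(tt.var_names) + [tt.name])
        for m in tt.minterms():
            w.writerow(list(m.bits) + [tt.outputs[m.index]])

    if hasattr(path_or_file, "write"):
        _write(path_or_file)
    else:
        with open(path_or_file, "w", newline="") as fh:
            _write(fh)


def read_table_csv(path_or_file) -> TruthTable:
    """Read a truth table, validating shape, bit values, and row order."""
    if hasattr(path_or_file, "read"):
        return _read_table(path_or_file)
    with open(path_or_file, newline="") as fh:
        return _read_table(fh)


def _read_table(fh) -> TruthTable:
    rows = list(csv.reader(fh))
    rows = [(i + 1, r) for i, r in enumerate(rows) if any(cell.strip() for cell in r)]
    if not rows:
        raise TableFormatError("empty truth-table file")
    _, header = rows[0]
    header = [h.strip() for h in header]
    if len(header) < 2:
        raise TableFormatError("header must list at least one variable and the "
                               "function name", line=rows[0][0])
    var_names, fname = tuple(header[:-1]), header[-1]
    n = len(var_names)
    data = rows[1:]
    if len(data) != 2 ** n:
        raise TableFormatError(
            f"expected {2 ** n} data rows for {n} variables, got {len(data)}")
    outputs = []
    for row_idx, (lineno, cells) in enumerate(data):
        cells = [c.strip() for c in cells]
        if len(cells) != n + 1:
            raise TableFormatError(
                f"expected {n + 1} columns, got {len(cells)}", line=lineno)
        try:
            bits = [int(c) for c in cells]
        except ValueError:
            raise TableFormatError(f"non-integer cell in {cells}", line=lineno) from None
        if any(b not in (0, 1) for b in bits):
            raise TableFormatError(f"cells must be 0/1, got {cells}", line=lineno)
        expected = tuple((row_idx >> (n - 1 - i)) & 1 for i in range(n))
        if tuple(bits[:-1]) != expected:
            raise TableFormatError(
                f"row out of canonical order: expected input bits "
                f"{expected}, got {tuple(bits[:-1])}", line=lineno)
        outputs.append(bits[-1])
    return TruthTable(var_names, tuple(outputs), name=fname)


def table_from_csv_text(text: str) -> TruthTable:
    """Convenience wrapper for reading a table from an in-memory string."""
    return _read_table(io.StringIO(text))
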