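"""Randomized-bitstream simulator: the sampling view of stochastic logic.

A value ``x`` is carried by a stream of i.i.d. Bernoulli(x) bits; applying
a truth table bitwise to independent streams yields a stream whose
one-probability is the table's stochastic function.  The empirical mean of
the output stream therefore converges (at binomial rate) to the closed-form
value, which makes this module an independent sampling oracle for the
analytic evaluation in :mod:`crnstoch.logic`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, DomainError
from .logic import ProbabilityAssignment, TruthTable, eval_stochastic_function

__all__ = ["Bitstream", "generate", "eval_table_on_streams", "streams_for_table"]

DEFAULT_LENGTH = 100_000


@dataclass(frozen=True)
class Bitstream:
    """A 0/1 sequence with its nominal one-probability and seed."""

    bits: np.ndarray
    p: float
    seed: int | None = None

    def __post_init__(self):
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.ndim != 1:
            raise ConfigurationError("bitstream must be one-dimensional")
        if np.any(bits > 1):
            raise ConfigurationError("bitstream values must be 0 or 1")
        object.__setattr__(self, "bits", bits)

    def __len__(self) -> int:
        return len(self.bits)

    @property
    def mean(self) -> float:
        return float(self.bits.mean())


def generate(p: float, length: int = DEFAULT_LENGTH, seed: int = 0) -> Bitstream:
    """An i.i.d. Bernoulli(p) stream, reproducible per seed."""
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"probability {p} outside [0, 1]")
    if length < 1:
        raise ConfigurationError(f"length must be positive, got {length}")
    rng = np.random.default_rng(seed)
    bits = (rng.random(length) < p).astype(np.uint8)
    return Bitstream(bits, float(p), seed)


def streams_for_table(tt: TruthTable, assignment, length: int = DEFAULT_LENGTH,
                      seed: int = 0) -> list[Bitstream]:
    """One independently seeded stream per table variable.

    Per-variable seeds are spawned from ``seed`` so the streams are
    uncorrelated — the independence assumption under which the closed form
    holds.  Bound variables (shared probability) still get independent
    streams.
    """
    if not isinstance(assignment, ProbabilityAssignment):
        assignment = ProbabilityAssignment(assignment)
    children = np.random.SeedSequence(seed).spawn(tt.n)
    return [
        Bitstream((np.random.default_rng(child).random(length)
                   < assignment[var]).astype(np.uint8), assignment[var],
                  int(child.entropy) % (2**31))
        for var, child in zip(tt.var_names, children)
    ]


def eval_table_on_streams(tt: TruthTable, streams: Sequence[Bitstream]
                          ) -> tuple[Bitstream, float]:
    """Apply the table bitwise; return the output stream and its mean."""
    if len(streams) != tt.n:
        raise ConfigurationError(
            f"table has {tt.n} variables but {len(streams)} streams given")
    lengths = {len(s) for s in streams}
    if len(lengths) != 1:
        raise ConfigurationError(f"stream lengths differ: {sorted(lengths)}")
    bits = np.stack([s.bits for s in streams])  # (n, L)
    weights = 1 << np.arange(tt.n - 1, -1, -1)  # first variable is the MSB
    rows = weights @ bits.astype(np.int64)
    out_bits = np.asarray(tt.outputs, dtype=np.uint8)[rows]
    exact = eval_stochastic_function(
        tt, {v: s.p for v, s in zip(tt.var_names, streams)})
    out = Bitstream(out_bits, exact, None)
    return out, out.mean
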