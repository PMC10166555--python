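"""Compile truth tables into chemical reaction networks over species pairs.

A value ``x`` in [0, 1] is represented *fractionally* by a pair of species:
``x = [X1] / ([X0] + [X1])``.  An n-input truth table compiles into a CRN
with one reaction per minterm, in canonical row order::

    X_{1,v1} + X_{2,v2} + ... + X_{n,vn}  ->k  Y_{F(V)}

i.e. 2^n reactions over 2n + 2 species.  When all rate constants are equal
the CRN computes the table's stochastic function exactly (see the kinetics
module for the dynamical argument); the compiler itself is purely
structural.

Also here: fractional encode/decode, fan-out volume planning, sequential
cascading of compiled stages, and a plain-text reaction format.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import (
    CascadeError,
    ConfigurationError,
    CrnFormatError,
    DomainError,
    UndefinedFractionError,
)
from .logic import TruthTable

__all__ = [
    "Species",
    "Reaction",
    "CRN",
    "FractionalState",
    "compile_table",
    "encode",
    "decode",
    "decode_pair",
    "FanoutPlan",
    "plan_fanout",
    "CascadePlan",
    "cascade",
    "format_crn",
    "parse_crn",
    "read_crn",
    "write_crn",
]

#: Study-condition defaults: rate constant and pair total used throughout.
DEFAULT_K = 100.0
DEFAULT_TOTAL = 100.0


@dataclass(frozen=True, order=True)
class Species:
    """A molecular species, optionally indexed as one half of a pair.

    Input/output pairs use indices 0 and 1; free-standing species (as in
    hand-written CRNs) may carry no index.
    """

    base: str
    index: int | None = None

    @property
    def name(self) -> str:
        return self.base if self.index is None else f"{self.base}_{self.index}"

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class Reaction:
    """reactants ->k products, with positive integer stoichiometry."""

    reactants: tuple[tuple[Species, int], ...]
    products: tuple[tuple[Species, int], ...]
    k: float = DEFAULT_K

    def __post_init__(self):
        if self.k <= 0:
            raise ConfigurationError(f"rate constant must be positive, got {self.k}")
        if not self.reactants or not self.products:
            raise ConfigurationError("a reaction needs at least one reactant and one product")
        for sp, coef in self.reactants + self.products:
            if coef < 1 or coef != int(coef):
                raise ConfigurationError(f"stoichiometry of {sp} must be a positive integer")

    def species(self) -> set[Species]:
        return {sp for sp, _ in self.reactants} | {sp for sp, _ in self.products}

    def __str__(self) -> str:
        def side(terms):
            return " + ".join(f"{c} {s}" if c > 1 else str(s) for s, c in terms)

        return f"{side(self.reactants)} -> {side(self.products)} ; k={self.k:g}"


@dataclass(frozen=True)
class CRN:
    """A reaction network plus the pair structure used for fractional I/O.

    ``input_pairs`` lists (X_0, X_1) in input order; ``output_pair`` is
    (Y_0, Y_1).  Either may be empty/None for hand-written networks.
    """

    species: tuple[Species, ...]
    reactions: tuple[Reaction, ...]
    input_pairs: tuple[tuple[Species, Species], ...] = ()
    output_pair: tuple[Species, Species] | None = None
    source: str = ""

    def __post_init__(self):
        if len(set(self.species)) != len(self.species):
            raise ConfigurationError("duplicate species in CRN")
        declared = set(self.species)
        used = set().union(*(r.species() for r in self.reactions)) if self.reactions else set()
        if not used <= declared:
            raise ConfigurationError(f"reactions use undeclared species: {sorted(s.name for s in used - declared)}")

    @property
    def n_inputs(self) -> int:
        return len(self.input_pairs)

    @property
    def var_names(self) -> tuple[str, ...]:
        return tuple(p[0].base for p in self.input_pairs)

    @property
    def function_name(self) -> str | None:
        return self.output_pair[0].base if self.output_pair else None

    def with_rates(self, rates: Sequence[float]) -> "CRN":
        """The same network with per-reaction rate constants replaced."""
        if len(rates) != len(self.reactions):
            raise ConfigurationError(
                f"need {len(self.reactions)} rates, got {len(rates)}")
        new = tuple(
            Reaction(r.reactants, r.products, float(k))
            for r, k in zip(self.reactions, rates)
        )
        return CRN(self.species, new, self.input_pairs, self.output_pair, self.source)

    @property
    def rates(self) -> tuple[float, ...]:
        return tuple(r.k for r in self.reactions)


@dataclass
class FractionalState:
    """Concentrations of all species, in arbitrary (but shared) units."""

    concentrations: dict[Species, float]

    def __post_init__(self):
        for sp, c in self.concentrations.items():
            if c < 0:
                raise ConfigurationError(f"negative concentration for {sp}: {c}")

    def __getitem__(self, sp: Species) -> float:
        return self.concentrations.get(sp, 0.0)

    def total(self, pair: tuple[Species, Species]) -> float:
        return self[pair[0]] + self[pair[1]]

    def fraction(self, pair: tuple[Species, Species]) -> float:
        return decode(self, pair)


def compile_table(tt: TruthTable, k: float | Sequence[float] = DEFAULT_K) -> CRN:
    """Compile a truth table into its minterm-template CRN.

    One reaction per row, in canonical row order; the reactants are the
    input species selected by the row's bits and the product is the output
    species indexed by the row's function value.  ``k`` is a single shared
    rate constant, or one rate per reaction for perturbation studies.
    """
    rates = [float(k)] * tt.n_rows if isinstance(k, (int, float)) else [float(v) for v in k]
    if len(rates) != tt.n_rows:
        raise ConfigurationError(f"need {tt.n_rows} rates, got {len(rates)}")
    pairs = tuple((Species(v, 0), Species(v, 1)) for v in tt.var_names)
    out_pair = (Species(tt.name, 0), Species(tt.name, 1))
    species = tuple(s for p in pairs for s in p) + out_pair
    reactions = []
    for m in tt.minterms():
        reactants = tuple((pairs[i][bit], 1) for i, (_, bit) in enumerate(m))
        product = ((out_pair[tt.outputs[m.index]], 1),)
        reactions.append(Reaction(reactants, product, rates[m.index]))
    return CRN(species, tuple(reactions), pairs, out_pair,
               source=f"truth table {tt.name!r} over {', '.join(tt.var_names)}")


# ---------------------------------------------------------------------------
# Fractional encoding
# ---------------------------------------------------------------------------


def encode(x: float, total: float = DEFAULT_TOTAL) -> tuple[float, float]:
    """Split ``total`` into ([X0], [X1]) = (total*(1-x), total*x)."""
    if not 0.0 <= x <= 1.0:
        raise DomainError(f"fraction {x} outside [0, 1]")
    if total <= 0:
        raise DomainError(f"pair total must be positive, got {total}")
    return total * (1.0 - x), total * x


def decode_pair(c0: float, c1: float) -> float:
    """The fraction c1 / (c0 + c1)."""
    tot = c0 + c1
    if tot <= 0:
        raise UndefinedFractionError(
            f"cannot decode fraction from pair total {tot}")
    return c1 / tot


def decode(state: FractionalState, pair: tuple[Species, Species]) -> float:
    """Decode the fraction carried by a species pair in a state."""
    return decode_pair(state[pair[0]], state[pair[1]])


def initial_state(crn: CRN, fractions: Mapping[str, float],
                  total: float | Mapping[str, float] = DEFAULT_TOTAL) -> FractionalState:
    """Encode input fractions into concentrations; output pair starts at 0.

    ``total`` may be a single pair total or a per-variable mapping.
    """
    conc: dict[Species, float] = {sp: 0.0 for sp in crn.species}
    for (s0, s1) in crn.input_pairs:
        var = s0.base
        if var not in fractions:
            raise ConfigurationError(f"no input fraction for variable {var!r}")
        t = total[var] if isinstance(total, Mapping) else total
        conc[s0], conc[s1] = encode(float(fractions[var]), t)
    return FractionalState(conc)


# ---------------------------------------------------------------------------
# Fan-out
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FanoutPlan:
    """Volume bookkeeping for feeding one output into several consumers.

    Inputs are scaled up by the consumer count so that the produced output
    volume can be split into equal parts; splitting divides totals but
    never changes the encoded fraction.
    """

    consumers: int
    base_total: float

    def __post_init__(self):
        if self.consumers < 1:
            raise ConfigurationError("consumer count must be >= 1")
        if self.base_total <= 0:
            raise ConfigurationError("base total must be positive")

    @property
    def scaled_total(self) -> float:
        return self.base_total * self.consumers

    def split(self, pair_conc: tuple[float, float]) -> list[tuple[float, float]]:
        c0, c1 = pair_conc
        part = (c0 / self.consumers, c1 / self.consumers)
        return [part] * self.consumers


def plan_fanout(consumers: int, base_total: float = DEFAULT_TOTAL) -> FanoutPlan:
    return FanoutPlan(consumers, base_total)


# ---------------------------------------------------------------------------
# Cascading
# ---------------------------------------------------------------------------


@dataclass
class CascadePlan:
    """Sequential execution plan for wired CRN stages.

    ``wiring`` maps an upstream output variable (function name) to the
    downstream input variable(s) it feeds.  Stages run to completion one at
    a time, in topological order; each decoded output is re-encoded (at the
    fan-out-scaled total) as the downstream input, which is the volumetric
    split idealized.
    """

    stages: tuple[CRN, ...]
    wiring: dict[str, tuple[str, ...]]
    order: tuple[int, ...]

    def consumers(self, fn_name: str) -> int:
        return max(1, len(self.wiring.get(fn_name, ())))

    def run(self, inputs: Mapping[str, float], total: float = DEFAULT_TOTAL,
            **simulate_kwargs):
        """Execute the plan; returns (final outputs dict, per-stage results)."""
        from .kinetics import simulate_to_completion

        available = dict(inputs)
        results = []
        final: dict[str, float] = {}
        for idx in self.order:
            crn = self.stages[idx]
            missing = [v for v in crn.var_names if v not in available]
            if missing:
                raise ConfigurationError(
                    f"stage {crn.function_name!r} missing inputs {missing}")
            fractions = {v: available[v] for v in crn.var_names}
            stage_total = total * self.consumers(crn.function_name)
            init = initial_state(crn, fractions, stage_total)
            res = simulate_to_completion(crn, init, **simulate_kwargs)
            y = res.outputs[crn.function_name]
            results.append(res)
            for target in self.wiring.get(crn.function_name, ()):
                available[target] = y
            final[crn.function_name] = y
        return final, results


def cascade(stages: Sequence[CRN], wiring: Mapping[str, str | Sequence[str]] | None = None
            ) -> CascadePlan:
    """Build a sequential execution plan; rejects cyclic wiring."""
    stages = tuple(stages)
    norm: dict[str, tuple[str, ...]] = {}
    for src, dst in (wiring or {}).items():
        norm[src] = (dst,) if isinstance(dst, str) else tuple(dst)
    producers = {crn.function_name: i for i, crn in enumerate(stages)}
    # stage dependency edges: producer -> consumer
    deps: dict[int, set[int]] = {i: set() for i in range(len(stages))}
    for src, dsts in norm.items():
        if src not in producers:
            raise CascadeError(f"wiring source {src!r} is not produced by any stage")
        for dst in dsts:
            for j, crn in enumerate(stages):
                if dst in crn.var_names:
                    deps[j].add(producers[src])
    order: list[int] = []
    state = {i: 0 for i in deps}  # 0 unvisited, 1 in progress, 2 done

    def visit(i: int):
        if state[i] == 1:
            raise CascadeError("cyclic wiring between stages")
        if state[i] == 2:
            return
        state[i] = 1
        for d in sorted(deps[i]):
            visit(d)
        state[i] = 2
        order.append(i)

    for i in range(len(stages)):
        visit(i)
    return CascadePlan(stages, norm, tuple(order))


# ---------------------------------------------------------------------------
# Plain-text reaction format
# ---------------------------------------------------------------------------
#
# One reaction per line: ``A_0 + B_1 -> C_0 ; k=100`` with stoichiometry as
# ``2 X_1``.  Header comments record the source and the pair structure::
#
#     # crnstoch reaction format v1
#     # source: truth table 'c' over a, b
#     # inputs: a b
#     # output: c

_TERM_RE = re.compile(r"^(?:(\d+)\s+)?([A-Za-z][A-Za-z0-9_]*)$")
_SPECIES_RE = re.compile(r"^(.*)_([01])$")

FORMAT_VERSION = "v1"


def _parse_species(token: str) -> Species:
    m = _SPECIES_RE.match(token)
    if m:
        return Species(m.group(1), int(m.group(2)))
    return Species(token, None)


def _parse_side(text: str, lineno: int) -> tuple[tuple[Species, int], ...]:
    terms = []
    for raw in text.split("+"):
        raw = raw.strip()
        m = _TERM_RE.match(raw)
        if not m:
            raise CrnFormatError(f"cannot parse term {raw!r}", line=lineno)
        coef = int(m.group(1)) if m.group(1) else 1
        terms.append((_parse_species(m.group(2)), coef))
    return tuple(terms)


def format_crn(crn: CRN, comment: str | None = None) -> str:
    lines = [f"# crnstoch reaction format {FORMAT_VERSION}"]
    if crn.source:
        lines.append(f"# source: {crn.source}")
    if comment:
        lines.append(f"# {comment}")
    if crn.input_pairs:
        lines.append("# inputs: " + " ".join(crn.var_names))
    if crn.output_pair:
        lines.append(f"# output: {crn.function_name}")
    lines.extend(str(r) for r in crn.reactions)
    return "\n".join(lines) + "\n"


def parse_crn(text: str) -> CRN:
    reactions: list[Reaction] = []
    input_vars: list[str] | None = None
    output_var: str | None = None
    source = ""
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("inputs:"):
                input_vars = body[len("inputs:"):].split()
            elif body.startswith("output:"):
                output_var = body[len("output:"):].strip()
            elif body.startswith("source:"):
                source = body[len("source:"):].strip()
            continue
        if ";" not in line or "->" not in line:
            raise CrnFormatError("expected 'reactants -> products ; k=<rate>'",
                                 line=lineno)
        body, _, ktext = line.partition(";")
        ktext = ktext.strip()
        if not ktext.startswith("k="):
            raise CrnFormatError(f"missing rate annotation in {ktext!r}", line=lineno)
        try:
            k = float(ktext[2:])
        except ValueError:
            raise CrnFormatError(f"bad rate {ktext[2:]!r}", line=lineno) from None
        left, _, right = body.partition("->")
        reactions.append(Reaction(_parse_side(left, lineno),
                                  _parse_side(right, lineno), k))

    seen: list[Species] = []
    for r in reactions:
        for sp, _ in r.reactants + r.products:
            if sp not in seen:
                seen.append(sp)

    def pair_for(var: str) -> tuple[Species, Species]:
        s0, s1 = Species(var, 0), Species(var, 1)
        return s0, s1

    if input_vars is None:
        # infer: reactant bases whose 0/1 pair both occur, in first-seen order
        bases = []
        reactant_sp = {sp for r in reactions for sp, _ in r.reactants}
        for sp in seen:
            if sp in reactant_sp and sp.index in (0, 1) and sp.base not in bases:
                bases.append(sp.base)
        input_vars = [b for b in bases]
    if output_var is None:
        product_bases = []
        product_sp = {sp for r in reactions for sp, _ in r.products}
        for sp in seen:
            if sp in product_sp and sp.index in (0, 1) and sp.base not in product_bases:
                product_bases.append(sp.base)
        product_bases = [b for b in product_bases if b not in input_vars]
        output_var = product_bases[0] if len(product_bases) == 1 else None

    input_pairs = tuple(pair_for(v) for v in input_vars)
    output_pair = pair_for(output_var) if output_var else None
    species = list(seen)
    for p in input_pairs:
        for sp in p:
            if sp not in species:
                species.append(sp)
    if output_pair:
        for sp in output_pair:
            if sp not in species:
                species.append(sp)
    return CRN(tuple(species), tuple(reactions), input_pairs, output_pair, source)


def write_crn(crn: CRN, path, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(format_crn(crn, comment))


def read_crn(path) -> CRN:
    with open(path) as fh:
        return parse_crn(fh.read())
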