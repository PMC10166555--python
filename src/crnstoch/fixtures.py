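"""Deterministic fixture generation: example truth tables plus the exact
values their stochastic functions take, for use in demos and tests.

All fixtures are generated programmatically; the ``examples`` kind emits
the canonical small tables (NOR, AND, a 3-input worked example, 3-input
XOR), ``gate`` any library gate, ``xor3`` the 3-input parity table used by
the robustness study, and ``random_table`` a seeded random table.
"""

from __future__ import annotations

import json
import random
from pathlib import Path

from . import __version__
from .errors import ConfigurationError
from .logic import (
    TruthTable,
    eval_stochastic_function,
    gate_library,
    random_table,
    truth_table_to_polynomial,
    write_table_csv,
)

__all__ = ["XOR3_TABLE", "DEMO3_TABLE", "generate_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("random_table", "gate", "xor3", "examples")

#: 3-input parity: f(x,y,z) = x + y + z - 2xy - 2xz - 2yz + 4xyz.
XOR3_TABLE = TruthTable(("x", "y", "z"), (0, 1, 1, 0, 1, 0, 0, 1), name="f")

#: 3-input worked example whose function simplifies to x3 + x1*x2*(1 - x3).
DEMO3_TABLE = TruthTable(("x1", "x2", "x3"), (0, 1, 0, 1, 0, 1, 1, 1), name="F")


def _expected_payload(tt: TruthTable, seed: int) -> dict:
    """Exact closed-form values at a few deterministic assignments."""
    rng = random.Random(seed)
    points = []
    for _ in range(5):
        assignment = {v: round(rng.random(), 6) for v in tt.var_names}
        points.append({"assignment": assignment,
                       "value": eval_stochastic_function(tt, assignment)})
    return {
        "table": tt.name,
        "var_names": list(tt.var_names),
        "outputs": list(tt.outputs),
        "polynomial": truth_table_to_polynomial(tt).to_text(),
        "evaluations": points,
        "metadata": {"crnstoch": __version__, "seed": seed},
    }


def generate_fixture(kind: str, n: int | None = None, seed: int = 0,
                     out_dir=".", gate: str | None = None) -> list[Path]:
    """Write truth-table CSV(s) plus an expected-value JSON; returns paths.

    Deterministic per seed.  ``n`` is required (and capped at 8) for
    ``random_table``; ``gate`` selects the table for the ``gate`` kind.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if kind == "random_table":
        if n is None:
            raise ConfigurationError("random_table fixtures need n")
        tables = [("random", random_table(n, seed))]
    elif kind == "gate":
        if gate is None:
            raise ConfigurationError("gate fixtures need a gate name")
        tables = [(gate.lower(), gate_library(gate))]
    elif kind == "xor3":
        tables = [("xor3", XOR3_TABLE)]
    elif kind == "examples":
        tables = [
            ("nor", gate_library("NOR")),
            ("and", gate_library("AND")),
            ("demo3", DEMO3_TABLE),
            ("xor3", XOR3_TABLE),
        ]
    else:
        raise ConfigurationError(
            f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")

    paths = []
    for label, tt in tables:
        csv_path = out / f"{label}.csv"
        write_table_csv(tt, csv_path)
        json_path = out / f"{label}_expected.json"
        json_path.write_text(json.dumps(_expected_payload(tt, seed), indent=2) + "\n")
        paths.extend([csv_path, json_path])
    return paths
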