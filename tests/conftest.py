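import random

import pytest
from hypothesis import HealthCheck, settings

import crnstoch as cs

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def xor3():
    return cs.XOR3_TABLE


@pytest.fixture(scope="session")
def demo3():
    return cs.DEMO3_TABLE


def random_assignment(tt, rng: random.Random, interior=False):
    """A random probability assignment for a table's variables."""
    lo, hi = (0.05, 0.95) if interior else (0.0, 1.0)
    return {v: lo + (hi - lo) * rng.random() for v in tt.var_names}


@pytest.fixture(scope="session")
def equal_rate_runs():
    """Fifty equal-rate runs of random tables with their closed-form values.

    Shared by the correctness and invariant checks so the ODE work is done
    once.  Returns a list of (table, assignment, exact, result) tuples.
    """
    rng = random.Random(20240917)
    runs = []
    for i in range(50):
        n = 1 + i % 4
        tt = cs.random_table(n, seed=1000 + i)
        if not any(tt.outputs) or all(tt.outputs):
            # constant tables exercise nothing dynamical; flip one row
            outputs = list(tt.outputs)
            outputs[rng.randrange(len(outputs))] ^= 1
            tt = cs.TruthTable(tt.var_names, tuple(outputs), name=tt.name)
        assignment = random_assignment(tt, rng, interior=True)
        exact = cs.eval_stochastic_function(tt, assignment)
        crn = cs.compile_table(tt, k=100.0)
        res = cs.simulate_assignment(crn, assignment, total=100.0, record=True)
        runs.append((tt, assignment, exact, res))
    return runs
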