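"""Mass-action kinetics: ODE generation, integration to completion, and
dynamical invariant diagnostics.

For a reaction ``sum_s a_s S -> sum_s b_s S`` with rate constant ``k``, the
mass-action velocity is ``k * prod_s [S]^a_s`` and each species changes at
``(b_s - a_s) * velocity``.  For a compiled minterm-template CRN with equal
rates, three facts follow from the rate equations and are exposed here as
runtime diagnostics:

* each input fraction ``p_i = [Xi_1]/([Xi_0]+[Xi_1])`` is constant in time,
* each input pair total ``q_i`` is nonincreasing (inputs are only consumed),
* ``q_i + (output pair total)`` is conserved (every reaction consumes one
  molecule of pair i and produces one output molecule),

and the decoded output equals the table's stochastic function at *any* time
with nonzero output — not only in the exhausted-input limit.  With unequal
rates the fraction invariance breaks, which is exactly what the robustness
module measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.integrate import odeint

from .compiler import CRN, FractionalState, Species, decode_pair
from .errors import SimulationError
from .logic import ProbabilityAssignment

__all__ = [
    "ODESystem",
    "build_odes",
    "SimulationResult",
    "simulate_to_completion",
    "InvariantDiagnostics",
    "compute_diagnostics",
]

DEFAULT_REL_TOL = 1e-8
DEFAULT_ABS_TOL = 1e-10
DEFAULT_COMPLETION_EPS = 1e-6
OUTPUT_STABILITY_TOL = 1e-8
#: Readout clip for negative integrator overshoot (never fed back).
NEG_CLIP = 1e-9


@dataclass
class ODESystem:
    """Vector field of a CRN under mass-action kinetics.

    Callable as ``f(t, c) -> dc/dt`` with ``c`` ordered like ``species``.
    ``reactant_matrix[j, s]`` and ``net_matrix[j, s]`` hold the reactant and
    net stoichiometry of species ``s`` in reaction ``j``.
    """

    species: tuple[Species, ...]
    reactant_matrix: np.ndarray
    net_matrix: np.ndarray
    rates: np.ndarray
    index: dict[Species, int] = field(init=False)

    def __post_init__(self):
        self.index = {sp: i for i, sp in enumerate(self.species)}
        # transpose cached for the rhs hot loop
        self._netT = np.ascontiguousarray(self.net_matrix.T)

    def velocities(self, c: np.ndarray) -> np.ndarray:
        return self.rates * np.prod(c ** self.reactant_matrix, axis=1)

    def __call__(self, t: float, c: np.ndarray) -> np.ndarray:
        return self._netT @ self.velocities(c)

    def rhs_ct(self, c: np.ndarray, t: float) -> np.ndarray:
        """odeint-style signature."""
        return self._netT @ self.velocities(c)

    def pack(self, state: FractionalState | Mapping[Species, float]) -> np.ndarray:
        conc = state.concentrations if isinstance(state, FractionalState) else state
        c = np.zeros(len(self.species))
        for sp, v in conc.items():
            c[self.index[sp]] = v
        return c

    def unpack(self, c: np.ndarray) -> FractionalState:
        clipped = np.where((c < 0) & (c >= -NEG_CLIP), 0.0, c)
        return FractionalState({sp: float(clipped[i]) for i, sp in enumerate(self.species)})


def build_odes(crn: CRN) -> ODESystem:
    """Mass-action derivative function for an arbitrary CRN."""
    ns, nr = len(crn.species), len(crn.reactions)
    index = {sp: i for i, sp in enumerate(crn.species)}
    R = np.zeros((nr, ns))
    N = np.zeros((nr, ns))
    for j, rx in enumerate(crn.reactions):
        for sp, coef in rx.reactants:
            R[j, index[sp]] += coef
            N[j, index[sp]] -= coef
        for sp, coef in rx.products:
            N[j, index[sp]] += coef
    rates = np.array([rx.k for rx in crn.reactions])
    return ODESystem(tuple(crn.species), R, N, rates)


@dataclass
class SimulationResult:
    """Trajectories, final state, and decoded outputs of one run."""

    crn: CRN
    times: np.ndarray
    traj: dict[Species, np.ndarray]
    final_state: FractionalState
    outputs: dict[str, float]
    completed_by: str  # "depletion" or "output_stable"
    t_final: float
    n_stages: int

    def fraction_series(self, pair: tuple[Species, Species]) -> np.ndarray:
        """Decoded fraction of a pair along the trajectory (nan where total 0)."""
        c0, c1 = self.traj[pair[0]], self.traj[pair[1]]
        tot = c0 + c1
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, c1 / np.maximum(tot, 1e-300), np.nan)

    def total_series(self, pair: tuple[Species, Species]) -> np.ndarray:
        return self.traj[pair[0]] + self.traj[pair[1]]


def _initial_horizon(sys: ODESystem, c0: np.ndarray, crn: CRN) -> float:
    n = max(crn.n_inputs, 1)
    total = max((c0[sys.index[p[0]]] + c0[sys.index[p[1]]] for p in crn.input_pairs),
                default=max(float(np.max(c0)), 1.0))
    total = max(total, 1e-12)
    kmax = float(np.max(sys.rates))
    # collision timescale for n-molecular reactions at the initial totals;
    # only an order-of-magnitude guess, the doubling loop does the rest
    return 10.0 / (kmax * total ** n)


def simulate_to_completion(
    crn: CRN,
    init: FractionalState | Mapping[Species, float],
    *,
    rel_tol: float = DEFAULT_REL_TOL,
    abs_tol: float = DEFAULT_ABS_TOL,
    completion_eps: float = DEFAULT_COMPLETION_EPS,
    max_doublings: int = 70,
    record: bool = True,
    samples_per_stage: int = 16,
) -> SimulationResult:
    """Integrate a CRN until its inputs are spent or its output has settled.

    The horizon starts at a collision-timescale heuristic and doubles until
    either every input-pair total has fallen to ``completion_eps`` times its
    initial value, or the decoded output changes by less than 1e-8 across a
    doubling.  A stiff-capable adaptive integrator (LSODA) is used with
    tight tolerances; negative overshoot is clipped only at readout.

    With ``record=True`` the trajectory is sampled geometrically within each
    doubling stage (hundreds of points across the run), which is what the
    diagnostics operate on.  Parameter sweeps switch recording off.
    """
    sys = build_odes(crn)
    c = sys.pack(init)
    c0 = c.copy()
    if crn.output_pair is not None:
        i0, i1 = sys.index[crn.output_pair[0]], sys.index[crn.output_pair[1]]
    else:
        i0 = i1 = None
    in_idx = [(sys.index[p[0]], sys.index[p[1]]) for p in crn.input_pairs]
    q0 = np.array([c0[a] + c0[b] for a, b in in_idx])
    active = q0 > 0

    times_acc = [np.array([0.0])]
    traj_acc = [c0[:, None]]

    t_lo = 0.0
    t_hi = _initial_horizon(sys, c0, crn)
    prev_y = None
    completed_by = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # lsoda chatter on extreme stiffness
        for stage in range(1, max_doublings + 1):
            if record:
                if t_lo == 0.0:
                    ts = np.linspace(0.0, t_hi, samples_per_stage + 1)
                else:
                    ts = np.geomspace(t_lo, t_hi, samples_per_stage + 1)
            else:
                ts = np.array([t_lo, t_hi])
            sol = odeint(sys.rhs_ct, c, ts, rtol=rel_tol, atol=abs_tol, mxstep=100000)
            c = sol[-1]
            if record:
                times_acc.append(ts[1:])
                traj_acc.append(sol[1:].T)
            q = np.array([c[a] + c[b] for a, b in in_idx])
            if np.all(q[active] <= completion_eps * q0[active]):
                completed_by = "depletion"
                break
            if i0 is not None:
                ytot = c[i0] + c[i1]
                y = c[i1] / ytot if ytot > 0 else None
                if (y is not None and prev_y is not None
                        and abs(y - prev_y) < OUTPUT_STABILITY_TOL):
                    completed_by = "output_stable"
                    break
                prev_y = y
            t_lo, t_hi = t_hi, 2.0 * t_hi
        else:
            raise SimulationError(
                f"no completion after {max_doublings} horizon doublings "
                f"(t = {t_hi:g}); input totals at {q / np.maximum(q0, 1e-300)} "
                "of initial",
                state={sp.name: float(v) for sp, v in zip(sys.species, c)},
            )

    final = sys.unpack(c)
    outputs = {}
    if crn.output_pair is not None:
        outputs[crn.function_name] = decode_pair(
            final[crn.output_pair[0]], final[crn.output_pair[1]])
    if record:
        times = np.concatenate(times_acc)
        mat = np.concatenate(traj_acc, axis=1)
        traj = {sp: mat[i] for i, sp in enumerate(sys.species)}
    else:
        times = np.array([0.0, t_hi])
        traj = {sp: np.array([c0[i], c[i]]) for i, sp in enumerate(sys.species)}
    return SimulationResult(crn, times, traj, final, outputs,
                            completed_by, float(t_hi), stage)


def simulate_assignment(
    crn: CRN,
    assignment: ProbabilityAssignment | Mapping[str, float],
    total: float = 100.0,
    **kwargs,
) -> SimulationResult:
    """Convenience: encode input fractions, simulate, decode."""
    from .compiler import initial_state

    if isinstance(assignment, ProbabilityAssignment):
        fractions = {v: assignment[v] for v in crn.var_names}
    else:
        fractions = dict(assignment)
    return simulate_to_completion(crn, initial_state(crn, fractions, total), **kwargs)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

#: Input fractions are checked for drift only while the pair retains this
#: share of its initial total; below it, round-off in the tiny residual
#: dominates the quotient and the statistic stops being informative.
P_DRIFT_MASK = 1e-4


@dataclass
class InvariantDiagnostics:
    """Time series and pass/fail flags for the equal-rate invariants.

    ``p[var]`` is the input fraction over time (nan once the pair is
    depleted past the drift mask), ``q[var]`` the pair total, ``l`` the
    product of all input totals (the shared factor in every reaction
    velocity), and ``conservation[var]`` the relative drift of
    ``q_var + q_output``.
    """

    times: np.ndarray
    p: dict[str, np.ndarray]
    q: dict[str, np.ndarray]
    l: np.ndarray
    conservation: dict[str, np.ndarray]
    p_drift: dict[str, float]
    p_invariant_ok: bool
    q_nonincreasing_ok: bool
    conservation_ok: bool

    @property
    def flags_raised(self) -> bool:
        return not (self.p_invariant_ok and self.q_nonincreasing_ok
                    and self.conservation_ok)

    def summary(self) -> dict:
        return {
            "max_p_drift": max(self.p_drift.values(), default=0.0),
            "p_invariant_ok": self.p_invariant_ok,
            "q_nonincreasing_ok": self.q_nonincreasing_ok,
            "conservation_ok": self.conservation_ok,
        }


def compute_diagnostics(
    result: SimulationResult,
    crn: CRN | None = None,
    *,
    p_tol: float = 1e-6,
    q_rise_tol: float = 1e-9,
    conservation_tol: float = 1e-6,
) -> InvariantDiagnostics:
    """Evaluate the dynamical invariants on a recorded run.

    Flags are raised (set False) when a tolerance is exceeded; for an
    equal-rate compiled CRN all three hold, while rate perturbations break
    the fraction invariance first.
    """
    crn = crn or result.crn
    times = result.times
    p: dict[str, np.ndarray] = {}
    q: dict[str, np.ndarray] = {}
    cons: dict[str, np.ndarray] = {}
    p_drift: dict[str, float] = {}
    q_out = (result.total_series(crn.output_pair)
             if crn.output_pair is not None else np.zeros_like(times))
    l = np.ones_like(times)
    p_ok = q_ok = c_ok = True
    for pair in crn.input_pairs:
        var = pair[0].base
        qi = result.total_series(pair)
        q[var] = qi
        l = l * qi
        q0 = qi[0]
        rises = np.diff(qi)
        if q0 > 0 and np.any(rises > q_rise_tol * q0):
            q_ok = False
        frac = result.fraction_series(pair)
        mask = qi > P_DRIFT_MASK * q0 if q0 > 0 else np.zeros_like(qi, dtype=bool)
        frac = np.where(mask, frac, np.nan)
        p[var] = frac
        drift = (float(np.nanmax(np.abs(frac - frac[0])))
                 if mask.any() and np.isfinite(frac[0]) else 0.0)
        p_drift[var] = drift
        if drift > p_tol:
            p_ok = False
        tot = qi + q_out
        ref = tot[0] if tot[0] > 0 else 1.0
        resid = (tot - tot[0]) / ref
        cons[var] = resid
        if np.max(np.abs(resid)) > conservation_tol:
            c_ok = False
    return InvariantDiagnostics(times, p, q, l, cons, p_drift, p_ok, q_ok, c_ok)
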