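"""Rate-constant robustness study: error cubes over the input lattice.

Equal rate constants are the correctness condition for compiled CRNs; this
module measures what happens when they are not equal.  A *rate scheme*
perturbs the per-reaction rates (one reaction scaled, or all rates drawn
from a normal distribution), and an *error cube* records, for every point
of a regular lattice over the unit hypercube of input fractions, the
absolute difference between the ODE-simulated output and the closed-form
stochastic function.  The summary statistics are the maximum error and the
percentage of lattice points whose error exceeds 0.1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .compiler import DEFAULT_TOTAL, compile_table, initial_state
from .errors import ConfigurationError, SimulationError
from .kinetics import simulate_to_completion
from .logic import TruthTable, eval_stochastic_function

__all__ = ["RateScheme", "make_rates", "ErrorCube", "error_cube", "summarize",
           "plot_error_cube"]

EXCEEDANCE_THRESHOLD = 0.1
SCHEME_KINDS = ("uniform", "single_scaled", "normal_random")


@dataclass(frozen=True)
class RateScheme:
    """How the per-reaction rate constants are produced.

    kinds
        ``uniform``: all rates equal ``base_k``.
        ``single_scaled``: rate of reaction ``target_reaction_index``
        (0-based, canonical row order) multiplied by ``factor``.
        ``normal_random``: rates drawn i.i.d. from Normal(base_k, sigma),
        redrawing nonpositive samples so every rate is strictly positive.
    """

    kind: str
    base_k: float = 100.0
    target_reaction_index: int = 0
    factor: float = 1.0
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in SCHEME_KINDS:
            raise ConfigurationError(
                f"unknown scheme kind {self.kind!r}; expected one of {SCHEME_KINDS}")
        if self.base_k <= 0:
            raise ConfigurationError(f"base rate must be positive, got {self.base_k}")
        if self.kind == "single_scaled" and self.factor <= 0:
            raise ConfigurationError(f"scale factor must be positive, got {self.factor}")
        if self.sigma < 0:
            raise ConfigurationError(f"sigma must be nonnegative, got {self.sigma}")

    @classmethod
    def uniform(cls, base_k: float = 100.0) -> "RateScheme":
        return cls("uniform", base_k=base_k)

    @classmethod
    def single_scaled(cls, base_k: float, index: int, factor: float) -> "RateScheme":
        return cls("single_scaled", base_k=base_k,
                   target_reaction_index=index, factor=factor)

    @classmethod
    def normal_random(cls, base_k: float, sigma: float, seed: int) -> "RateScheme":
        return cls("normal_random", base_k=base_k, sigma=sigma, seed=seed)

    def describe(self) -> str:
        if self.kind == "uniform":
            return f"uniform k={self.base_k:g}"
        if self.kind == "single_scaled":
            return (f"k[{self.target_reaction_index}]="
                    f"{self.base_k * self.factor:g}, others {self.base_k:g}")
        return f"k ~ Normal({self.base_k:g}, {self.sigma:g}), seed {self.seed}"


def make_rates(scheme: RateScheme, n_reactions: int) -> np.ndarray:
    """Realize a scheme as a vector of strictly positive rate constants."""
    if scheme.kind == "uniform":
        return np.full(n_reactions, scheme.base_k)
    if scheme.kind == "single_scaled":
        if not 0 <= scheme.target_reaction_index < n_reactions:
            raise ConfigurationError(
                f"target reaction index {scheme.target_reaction_index} out of "
                f"range for {n_reactions} reactions")
        rates = np.full(n_reactions, scheme.base_k)
        rates[scheme.target_reaction_index] *= scheme.factor
        return rates
    rng = np.random.default_rng(scheme.seed)
    rates = rng.normal(scheme.base_k, scheme.sigma, size=n_reactions)
    # nonpositive draws are redrawn rather than truncated, which keeps the
    # realized mean close to base_k
    while np.any(rates <= 0):
        bad = rates <= 0
        rates[bad] = rng.normal(scheme.base_k, scheme.sigma, size=int(bad.sum()))
    return rates


@dataclass
class ErrorCube:
    """|simulated - expected| on a regular lattice of input fractions.

    ``grid`` holds the per-axis lattice values (shared across axes);
    ``errors`` has shape ``(len(grid),) * n`` with axes in variable order.
    """

    grid: np.ndarray
    errors: np.ndarray
    scheme: RateScheme
    table_name: str
    var_names: tuple[str, ...]
    pair_total: float
    rates: np.ndarray = field(default=None)

    @property
    def summary(self) -> tuple[float, float]:
        return summarize(self)

    @property
    def max_error(self) -> float:
        return float(self.errors.max())

    @property
    def percent_exceeding(self) -> float:
        return summarize(self)[1]

    def face_interior_means(self) -> tuple[float, float]:
        """Mean error on lattice faces (some coordinate at 0 or 1) vs interior."""
        n = self.errors.ndim
        m = len(self.grid)
        face = np.zeros(self.errors.shape, dtype=bool)
        for axis in range(n):
            sl = [slice(None)] * n
            for edge in (0, m - 1):
                sl[axis] = edge
                face[tuple(sl)] = True
        return float(self.errors[face].mean()), float(self.errors[~face].mean())


def _lattice(step: float) -> np.ndarray:
    m = 1.0 / step
    if abs(m - round(m)) > 1e-9:
        raise ConfigurationError(f"step {step} does not divide 1 evenly")
    return np.round(np.linspace(0.0, 1.0, int(round(m)) + 1), 12)


def error_cube(
    tt: TruthTable,
    scheme: RateScheme,
    step: float = 0.1,
    pair_total: float = DEFAULT_TOTAL,
    **simulate_kwargs,
) -> ErrorCube:
    """Simulate the compiled CRN at every lattice point and record errors.

    Each point encodes the input fractions at ``pair_total`` per pair,
    integrates the CRN to completion, decodes the output, and compares with
    the closed-form stochastic function.  Non-convergence at a point is
    re-raised with the lattice coordinates attached.
    """
    grid = _lattice(step)
    rates = make_rates(scheme, tt.n_rows)
    crn = compile_table(tt, rates)
    shape = (len(grid),) * tt.n
    errors = np.empty(shape)
    simulate_kwargs.setdefault("record", False)
    for idx in itertools.product(range(len(grid)), repeat=tt.n):
        point = {v: float(grid[i]) for v, i in zip(tt.var_names, idx)}
        expected = eval_stochastic_function(tt, point)
        init = initial_state(crn, point, pair_total)
        try:
            res = simulate_to_completion(crn, init, **simulate_kwargs)
        except SimulationError as exc:
            raise SimulationError(str(exc), state=exc.state, context=point) from exc
        errors[idx] = abs(res.outputs[tt.name] - expected)
    return ErrorCube(grid, errors, scheme, tt.name, tt.var_names, pair_total,
                     rates=rates)


def summarize(cube: ErrorCube, threshold: float = EXCEEDANCE_THRESHOLD
              ) -> tuple[float, float]:
    """(max error, percent of lattice points with error strictly > threshold)."""
    if cube.errors.size == 0:
        raise ConfigurationError("cannot summarize an empty error cube")
    max_error = float(cube.errors.max())
    percent = 100.0 * float(np.count_nonzero(cube.errors > threshold)) / cube.errors.size
    return max_error, percent


def plot_error_cube(cube: ErrorCube, path=None):
    """Render axis-2 slices of a 3-input cube as a row of heatmaps.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if cube.errors.ndim != 3:
        raise ConfigurationError("slice plotting expects a 3-input cube")
    m = len(cube.grid)
    fig, axes = plt.subplots(1, m, figsize=(2.2 * m, 2.6), sharey=True)
    vmax = max(cube.max_error, 1e-6)
    for i, ax in enumerate(np.atleast_1d(axes)):
        im = ax.imshow(cube.errors[:, :, i].T, origin="lower", vmin=0, vmax=vmax,
                       extent=(0, 1, 0, 1), cmap="viridis")
        ax.set_title(f"{cube.var_names[2]}={cube.grid[i]:.1f}", fontsize=8)
        ax.set_xlabel(cube.var_names[0], fontsize=8)
    np.atleast_1d(axes)[0].set_ylabel(cube.var_names[1], fontsize=8)
    fig.colorbar(im, ax=axes, shrink=0.8, label="|error|")
    fig.suptitle(f"{cube.table_name}: {cube.scheme.describe()}", fontsize=9)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
    return fig
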