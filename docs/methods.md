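# Methods

## Model

A truth table `F(X₁,…,Xₙ)` induces a stochastic function: with each input
`Xᵢ` an independent Bernoulli(xᵢ) variable, the output is Bernoulli with
parameter

```
f(x) = Σ_{V: F(V)=1} Π_h c_{h,v_h},   c_{h,1} = x_h,  c_{h,0} = 1 − x_h.
```

Expanding the products gives a multilinear polynomial with integer
coefficients; `crnstoch` stores these exactly and evaluates either form.
Every table rounds-trips through its polynomial via vertex evaluation, and
a polynomial whose vertex values are not Boolean (tolerance 1e−9) is
rejected as not implementable by a single table.

The molecular encoding is fractional: `x = [X₁]/([X₀]+[X₁])` over a species
pair. The compiler emits one reaction per minterm, in canonical row order
(rows ascend as binary integers, first listed variable most significant):
the n reactant species are selected by the row's bits, and the single
product is the output species indexed by the row's function value. This
gives `2ⁿ` reactions over `2n + 2` species; the structure is feed-forward
(inputs are only consumed, outputs only produced).

Under mass-action kinetics with all rate constants equal, three exact
properties follow from the rate equations, and the package checks them
numerically on every recorded run:

* each input fraction `pᵢ(t)` is constant (`dpᵢ/dt = 0`);
* each input pair total `qᵢ(t)` is nonincreasing, with all pairs losing
  mass at the identical rate `k·Π_h q_h`;
* `qᵢ + (output total)` is conserved pair-by-pair, since every reaction
  consumes one molecule of each input pair and produces one output
  molecule.

Consequently the decoded output `y = [Y₁]/([Y₀]+[Y₁])` equals `f(x)` at
*every* time with nonzero output mass, not only in the exhausted-input
limit. Unequal rates break the fraction invariance — the input composition
drifts toward the slow reactions' reactants — and the output acquires a
systematic bias. That bias is the subject of the robustness study.

## Numerical integration

`build_odes` assembles the mass-action vector field for an arbitrary
network from its reactant and net stoichiometry matrices
(velocity `k·Π [S]^a`). `simulate_to_completion` integrates with LSODA
(stiff-capable, adaptive; rel_tol 1e−8, abs_tol 1e−10 by default).

There is no natural final time: input depletion is a power law
(`q ∝ t^{−1/(n−1)}` for n ≥ 2), so "completion" is defined operationally.
The horizon starts at the collision-timescale guess `10/(k_max·total^n)`
and doubles until either

* every input pair total has fallen to 1e−6 of its initial value, or
* the decoded output changes by less than 1e−8 across one doubling.

The second criterion is what usually fires for equal-rate networks (whose
output fraction is constant in time); perturbed networks typically run to
depletion. Seventy doublings without either criterion raises an error
carrying the last state. Negative integrator overshoot is clipped to zero
at readout only, never fed back into the state. Trajectories are sampled
geometrically within each doubling stage (16 samples per stage, hundreds
per run) for the diagnostics; parameter sweeps skip recording.

Diagnostic tolerances: fraction drift ≤ 1e−6 (evaluated while a pair
retains at least 1e−4 of its initial total — below that, round-off in the
tiny residual dominates the quotient), pair-total rises ≤ 1e−9 relative,
conservation drift ≤ 1e−6 relative.

## Robustness study

The 3-input XOR table (`f = x + y + z − 2xy − 2xz − 2yz + 4xyz`) is the
stress case: its output column is balanced between 0s and 1s, so rate
mismatches cannot hide in an unbalanced product the way they can for AND
or OR. Rate schemes: `uniform` (all equal), `single_scaled` (one reaction's
rate multiplied by a factor; index 0 — the all-zeros minterm reaction — by
default), and `normal_random` (i.i.d. Normal(base, σ), redrawing
nonpositive samples; redraw rather than flooring keeps the realized mean
near the base for small σ, though conditioning on positivity shifts it up
~11% at σ = 70).

An error cube fixes a scheme, compiles the network once, then for every
point of the lattice `{0, 0.1, …, 1}ⁿ` (both endpoints included; 1331
points for n = 3) encodes the inputs at pair total 100, simulates to
completion, and records `|decoded − f(x)|`. The summary is the maximum
error and the percentage of points with error *strictly* above 0.1.

Study conditions are fixed at base rate k = 100 and pair total 100; they
are the package defaults. Both deterministic perturbation sweeps (factors
10, 1/10, 100, 1/100) reproduce bit-identically across runs; the random
schemes are reproducible per seed.

## Bitstream oracle

The bitstream module is an independent *sampling* route to the same
quantity: one seeded generator per variable (independent streams — the
assumption under which the closed form holds), bitwise table application,
empirical mean. Agreement within a few binomial standard errors at stream
length 1e5 checks the analytic evaluation without sharing any code path
with it. NOT is mean-complementary exactly, per stream, not just in
expectation.

## Design choices

* **Row/rate indexing.** Reaction j corresponds to minterm j in canonical
  row order; perturbation index 0 therefore targets the all-zeros reaction.
  For XOR-3 the choice is immaterial: complementing any two inputs (or all
  inputs plus the output) maps any single-reaction perturbation onto any
  other while permuting the lattice, so the error statistics coincide.
* **Cascading.** Stages run to completion sequentially; each decoded
  output is re-encoded as the downstream input at the fan-out-scaled pair
  total (the idealized volumetric split, which changes totals but never
  fractions). Concurrent one-pot operation of several stages is not
  modeled.
* **Replicated variables.** For univariate targets built from several
  copies of one input, each table column stays an independent species pair
  initialized at the shared value (`ProbabilityAssignment.bindings`);
  collapsing copies into squared-stoichiometry reactants would change the
  kinetics and is deliberately not done.
* **Exactness.** Table-derived polynomial coefficients are integers and
  compared exactly; Booleanness and fraction checks use 1e−9.

## Problem sizes

The default verification suite uses 50 random tables (n ≤ 4) for the
correctness property, the full 11³ lattice for the four deterministic
perturbation sweeps, a 6³ lattice across 20 seeds for the random-scheme
orderings, and 3 seeds of the σ = 10 scheme at full lattice in the
reproduction script. A full 11³ sweep is ~1331 stiff ODE solves and takes
on the order of half a minute.

## Limitations

* The kinetics are deterministic mass-action ODEs; stochastic (SSA)
  effects at small copy number, reversibility, temperature and volume
  dynamics are out of scope.
* The compiled networks are abstract: n-molecular reactions for n-input
  tables are taken at face value rather than decomposed into elementary
  bimolecular steps, and no physical chassis (e.g. strand displacement)
  is simulated.
* Lattice summaries quantify error only at grid resolution 0.1 unless a
  finer step is requested; maxima between grid points are not bounded.
* The closed form assumes independent inputs; correlated input streams or
  species are not modeled.
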