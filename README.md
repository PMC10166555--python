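# crnstoch

Stochastic logic with chemical reaction networks: compile any Boolean truth
table into an abstract mass-action reaction network that computes the
table's *stochastic function* on analog values carried by molecular
concentrations, simulate its kinetics, and quantify how the computation
degrades when reaction rate constants are perturbed.

## The idea

In stochastic logic a real value `x ∈ [0, 1]` is represented by a random
bitstream whose bits are 1 with probability `x`. Feeding independent
streams through a combinational function `F(X₁,…,Xₙ)` produces a stream
whose one-probability is the multilinear polynomial

```
f(x₁,…,xₙ) = Σ_{V ∈ S₁} Π_h c_{h,v_h},     c_{h,1} = x_h,  c_{h,0} = 1 − x_h,
```

the sum of the probabilities of the minterms `V` on which `F` evaluates
to 1. A single AND gate multiplies; small circuits compute surprisingly
rich functions.

The molecular analogue represents `x` *fractionally* with a pair of
species: `x = [X₁] / ([X₀] + [X₁])`. A truth table with `n` inputs then
compiles into a network of `2ⁿ` reactions over `2n + 2` species, one
reaction per minterm:

```
X_{1,v₁} + X_{2,v₂} + … + X_{n,vₙ}  →k  Y_{F(V)}
```

When all rate constants `k` are equal, each input fraction is invariant in
time and the decoded output `y = [Y₁]/([Y₀]+[Y₁])` equals `f(x₁,…,xₙ)` at
*any* time with nonzero output — not just in the exhausted-input limit.
With unequal rates that guarantee breaks down, and the `robustness` module
maps out by how much, on a lattice of input fractions.

## Worked example

```python
import crnstoch as cs

# an AND gate is a multiplier: c = a*b
tt = cs.gate_library("AND")
print(cs.truth_table_to_polynomial(tt).to_text())   # a*b

crn = cs.compile_table(tt, k=100.0)                 # 4 reactions, 6 species
res = cs.simulate_assignment(crn, {"a": 0.7, "b": 0.6}, total=100.0)
print(round(res.outputs["c"], 4))                   # 0.42

# break the equal-rate condition: double the rate of a_1 + b_1 -> c_1
crn2 = cs.compile_table(tt, [100.0, 100.0, 100.0, 200.0])
res2 = cs.simulate_assignment(crn2, {"a": 0.7, "b": 0.6})
print(round(res2.outputs["c"], 4))                  # 0.4625
```

The first simulation decodes `0.42 = 0.7 × 0.6`, the exact product. Doubling
one rate constant biases the output to `0.4625` — a 10% error from a single
2× rate mismatch, which is why equal rates are the correctness condition.

The same workflow from the shell:

```bash
crnstoch fixtures --kind examples -o demo/
crnstoch compile demo/and.csv -o demo/and.crn
crnstoch simulate demo/and.crn -x a=0.7 -x b=0.6
crnstoch bitstream demo/and.csv -p a=0.7 -p b=0.6 -L 100000 --seed 1
crnstoch errorcube demo/xor3.csv --kind single_scaled --factor 10 --step 0.1
```

`bitstream` cross-checks the closed form by actually sampling random
bitstreams; `errorcube` sweeps input fractions over a lattice and reports
the maximum simulation-vs-closed-form error and the percentage of lattice
points with error above 0.1.

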