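"""CRN compilation, fractional encoding, fan-out, cascades, and text I/O."""

import pytest
from hypothesis import given, strategies as st

import crnstoch as cs
from crnstoch.compiler import Species
from crnstoch.errors import (
    CascadeError,
    ConfigurationError,
    CrnFormatError,
    DomainError,
    UndefinedFractionError,
)


def reaction_signature(rx):
    """((base, index), ...) -> (base, index) for single-product reactions."""
    reactants = tuple((sp.base, sp.index) for sp, c in rx.reactants for _ in range(c))
    (product, _), = rx.products
    return reactants, (product.base, product.index)


class TestCompile:
    def test_nor_reactions(self):
        crn = cs.compile_table(cs.gate_library("NOR"), k=100)
        got = [reaction_signature(r) for r in crn.reactions]
        assert got == [
            ((("a", 0), ("b", 0)), ("c", 1)),
            ((("a", 0), ("b", 1)), ("c", 0)),
            ((("a", 1), ("b", 0)), ("c", 0)),
            ((("a", 1), ("b", 1)), ("c", 0)),
        ]

    def test_and_last_reaction_produces_one(self):
        crn = cs.compile_table(cs.gate_library("AND"))
        got = [reaction_signature(r) for r in crn.reactions]
        assert got[-1] == ((("a", 1), ("b", 1)), ("c", 1))
        assert [sig[1][1] for sig in got] == [0, 0, 0, 1]

    def test_xor3_reactions(self, xor3):
        crn = cs.compile_table(xor3)
        got = [reaction_signature(r) for r in crn.reactions]
        bits = [(0, 0, 0), (0, 0, 1), (0, 1, 0), (0, 1, 1),
                (1, 0, 0), (1, 0, 1), (1, 1, 0), (1, 1, 1)]
        outs = [0, 1, 1, 0, 1, 0, 0, 1]
        expected = [
            (tuple(zip(("x", "y", "z"), b)), ("f", o))
            for b, o in zip(bits, outs)
        ]
        assert got == expected

    @pytest.mark.parametrize("n", range(1, 7))
    def test_size_scaling(self, n):
        tt = cs.random_table(n, seed=n)
        crn = cs.compile_table(tt)
        assert len(crn.reactions) == 2 ** n
        assert len(crn.species) == 2 * n + 2

    @pytest.mark.parametrize("seed", range(5))
    def test_index_fidelity(self, seed):
        """Reactant indices equal the minterm bits; product index the output."""
        tt = cs.random_table(3, seed=seed)
        crn = cs.compile_table(tt)
        for m, rx in zip(tt.minterms(), crn.reactions):
            reactants, (_, out_idx) = reaction_signature(rx)
            assert tuple(idx for _, idx in reactants) == m.bits
            assert out_idx == tt.outputs[m.index]

    def test_per_reaction_rates(self, xor3):
        rates = [1000.0] + [100.0] * 7
        crn = cs.compile_table(xor3, rates)
        assert crn.rates == tuple(rates)
        with pytest.raises(ConfigurationError):
            cs.compile_table(xor3, [100.0] * 3)


class TestEncodeDecode:
    @pytest.mark.parametrize("x,total,expected", [
        (0.7, 100, (30, 70)),
        (0.0, 50, (50, 0)),
        (1.0, 50, (0, 50)),
    ])
    def test_encode(self, x, total, expected):
        assert cs.encode(x, total) == pytest.approx(expected)

    def test_encode_domain_error(self):
        with pytest.raises(DomainError):
            cs.encode(1.2, 100)
        with pytest.raises(DomainError):
            cs.encode(0.5, 0)

    def test_decode(self):
        assert cs.decode_pair(58, 42) == pytest.approx(0.42)
        assert cs.decode_pair(0, 7) == 1.0

    def test_decode_zero_total_is_distinct_error(self):
        with pytest.raises(UndefinedFractionError):
            cs.decode_pair(0.0, 0.0)
        assert not issubclass(UndefinedFractionError, DomainError)

    @given(st.floats(0, 1), st.floats(1e-6, 1e6))
    def test_round_trip(self, x, total):
        c0, c1 = cs.encode(x, total)
        assert cs.decode_pair(c0, c1) == pytest.approx(x, abs=1e-12)


class TestFanout:
    def test_scaling_and_split(self):
        plan = cs.plan_fanout(4, 100)
        assert plan.scaled_total == 400
        parts = plan.split((116, 84))
        assert len(parts) == 4
        assert all(p == (29.0, 21.0) for p in parts)

    def test_identity(self):
        plan = cs.plan_fanout(1, 100)
        assert plan.scaled_total == 100
        assert plan.split((58, 42)) == [(58, 42)]

    def test_split_preserves_fraction(self):
        plan = cs.plan_fanout(2, 100)
        for part in plan.split((116, 84)):
            assert cs.decode_pair(*part) == pytest.approx(0.42)
        assert plan.split((116, 84))[0] == (58.0, 42.0)


class TestCascade:
    def test_and_then_not_computes_nand(self):
        and_crn = cs.compile_table(cs.gate_library("AND"))
        not_tt = cs.TruthTable(("u",), (1, 0), name="y")
        plan = cs.cascade([and_crn, cs.compile_table(not_tt)], {"c": "u"})
        final, results = plan.run({"a": 0.7, "b": 0.6})
        assert final["y"] == pytest.approx(1 - 0.42, abs=1e-3)
        assert len(results) == 2

    def test_xor_then_not_at_half(self):
        xor_crn = cs.compile_table(cs.gate_library("XOR"))
        not_tt = cs.TruthTable(("u",), (1, 0), name="y")
        plan = cs.cascade([xor_crn, cs.compile_table(not_tt)], {"c": "u"})
        final, _ = plan.run({"a": 0.5, "b": 0.5})
        assert final["y"] == pytest.approx(0.5, abs=1e-3)

    def test_single_stage_matches_direct_simulation(self):
        crn = cs.compile_table(cs.gate_library("OR"))
        plan = cs.cascade([crn])
        final, _ = plan.run({"a": 0.3, "b": 0.4})
        direct = cs.simulate_assignment(crn, {"a": 0.3, "b": 0.4})
        assert final["c"] == pytest.approx(direct.outputs["c"], abs=1e-9)

    def test_fanout_scales_upstream_totals(self):
        and_crn = cs.compile_table(cs.gate_library("AND"))
        n1 = cs.compile_table(cs.TruthTable(("u",), (1, 0), name="y1"))
        n2 = cs.compile_table(cs.TruthTable(("w",), (1, 0), name="y2"))
        plan = cs.cascade([and_crn, n1, n2], {"c": ("u", "w")})
        assert plan.consumers("c") == 2
        final, results = plan.run({"a": 0.7, "b": 0.6}, total=100)
        # upstream stage ran at doubled totals, downstream at base totals
        and_res = results[plan.order.index(0)]
        assert sum(and_res.traj[sp][0] for sp in and_res.traj
                   if sp.base == "a") == pytest.approx(200)
        assert final["y1"] == pytest.approx(0.58, abs=1e-3)
        assert final["y2"] == pytest.approx(0.58, abs=1e-3)

    def test_cyclic_wiring_rejected(self):
        g1 = cs.compile_table(cs.TruthTable(("p",), (1, 0), name="q"))
        g2 = cs.compile_table(cs.TruthTable(("q",), (1, 0), name="p"))
        with pytest.raises(CascadeError):
            cs.cascade([g1, g2], {"q": "q", "p": "p"})


class TestTextFormat:
    def test_round_trip(self, xor3):
        crn = cs.compile_table(xor3, [1000.0] + [100.0] * 7)
        text = cs.format_crn(crn)
        back = cs.parse_crn(text)
        assert back.reactions == crn.reactions
        assert back.input_pairs == crn.input_pairs
        assert back.output_pair == crn.output_pair

    def test_stoichiometry_and_plain_species(self):
        text = "3 X3 + X4 -> X1 ; k=2.5\n"
        crn = cs.parse_crn(text)
        (rx,) = crn.reactions
        assert rx.reactants == ((Species("X3"), 3), (Species("X4"), 1))
        assert rx.k == 2.5
        assert "3 X3" in str(rx)

    def test_pair_inference_without_headers(self):
        text = ("a_0 + b_0 -> c_1 ; k=100\na_0 + b_1 -> c_0 ; k=100\n"
                "a_1 + b_0 -> c_0 ; k=100\na_1 + b_1 -> c_0 ; k=100\n")
        crn = cs.parse_crn(text)
        assert crn.var_names == ("a", "b")
        assert crn.function_name == "c"

    def test_parse_error_carries_line_number(self):
        with pytest.raises(CrnFormatError, match="line 2"):
            cs.parse_crn("a_0 + b_0 -> c_1 ; k=100\nnot a reaction\n")
        with pytest.raises(CrnFormatError, match="line 1"):
            cs.parse_crn("a_0 -> c_1 ; rate=3\n")
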