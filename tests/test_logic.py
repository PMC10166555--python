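"""Truth tables, closed-form evaluation, and multilinear polynomials."""

import io
import itertools
import random

import pytest
from hypothesis import given, strategies as st

import crnstoch as cs
from crnstoch.errors import (
    ConfigurationError,
    NotBooleanError,
    TableFormatError,
    UnknownGateError,
)
from crnstoch.logic import MultilinearPolynomial, table_from_csv_text

from conftest import random_assignment


class TestTruthTable:
    def test_row_order_first_variable_most_significant(self):
        tt = cs.TruthTable(("x1", "x2", "x3"), (0,) * 8)
        assert tt.minterm(0).bits == (0, 0, 0)
        assert tt.minterm(1).bits == (0, 0, 1)
        assert tt.minterm(4).bits == (1, 0, 0)
        assert tt.minterm(6).index == 6

    def test_s1_s0_partition(self, xor3):
        ones, zeros = xor3.ones(), xor3.zeros()
        assert {m.index for m in ones} | {m.index for m in zeros} == set(range(8))
        assert {m.index for m in ones} == {1, 2, 4, 7}

    @pytest.mark.parametrize("var_names,outputs", [
        ((), ()),                       # zero inputs rejected
        (("a",), (0, 1, 1)),            # wrong row count
        (("a", "a"), (0, 0, 0, 1)),     # duplicate names
        (("a", "b"), (0, 0, 2, 1)),     # non-Boolean output
    ])
    def test_invalid_tables_rejected(self, var_names, outputs):
        with pytest.raises(ConfigurationError):
            cs.TruthTable(var_names, outputs)


class TestMintermProbability:
    @pytest.mark.parametrize("probs,bits,expected", [
        ((0.5, 0.5, 0.5), (0, 0, 1), 0.125),
        ((0.7, 0.6), (1, 1), 0.42),
        ((0.3, 0.9, 0.2), (0, 1, 0), 0.7 * 0.9 * 0.8),
    ])
    def test_product_form(self, probs, bits, expected):
        names = tuple(f"x{i}" for i in range(len(bits)))
        m = cs.Minterm(bits, names)
        got = cs.minterm_probability(dict(zip(names, probs)), m)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_missing_variable_is_configuration_error(self):
        m = cs.Minterm((1, 0), ("a", "b"))
        with pytest.raises(ConfigurationError):
            cs.minterm_probability({"a": 0.5}, m)

    @given(st.integers(0, 2**16 - 1), st.lists(st.floats(0, 1), min_size=4, max_size=4))
    def test_normalization_over_all_minterms(self, table_bits, xs):
        """Minterm probabilities sum to one over any full table."""
        tt = cs.TruthTable(("a", "b", "c", "d"),
                           tuple((table_bits >> i) & 1 for i in range(16)))
        assignment = dict(zip(tt.var_names, xs))
        total = sum(cs.minterm_probability(assignment, m) for m in tt.minterms())
        assert total == pytest.approx(1.0, abs=1e-12)


class TestStochasticFunction:
    def test_nor_at_origin(self):
        assert cs.eval_stochastic_function(cs.gate_library("NOR"),
                                           {"a": 0, "b": 0}) == 1

    def test_and_multiplies(self):
        got = cs.eval_stochastic_function(cs.gate_library("AND"),
                                          {"a": 0.7, "b": 0.6})
        assert got == pytest.approx(0.42, abs=1e-12)

    def test_xor3_balanced_point(self, xor3):
        got = cs.eval_stochastic_function(xor3, {"x": 0.5, "y": 0.5, "z": 0.5})
        assert got == pytest.approx(0.5, abs=1e-12)

    def test_agreement_with_expanded_polynomial(self):
        rng = random.Random(7)
        for _ in range(10):
            tt = cs.random_table(3, seed=rng.randrange(10**6))
            poly = cs.truth_table_to_polynomial(tt)
            for _ in range(10):
                a = random_assignment(tt, rng)
                assert poly.evaluate(a) == pytest.approx(
                    cs.eval_stochastic_function(tt, a), abs=1e-10)

    def test_worked_example_simplification(self, demo3):
        """The 3-input demo table's function equals (1-x2)x3 + x2x3 + x1x2(1-x3)."""
        rng = random.Random(11)
        for _ in range(25):
            a = random_assignment(demo3, rng)
            x1, x2, x3 = a["x1"], a["x2"], a["x3"]
            expected = (1 - x2) * x3 + x2 * x3 + x1 * x2 * (1 - x3)
            assert cs.eval_stochastic_function(demo3, a) == pytest.approx(
                expected, abs=1e-12)

    def test_bindings_share_one_value(self):
        tt = cs.gate_library("AND")
        a = cs.ProbabilityAssignment({"u": 0.3}, bindings={"a": "u", "b": "u"})
        assert cs.eval_stochastic_function(tt, a) == pytest.approx(0.09)


class TestPolynomials:
    def test_xor3_expansion(self, xor3):
        p = cs.truth_table_to_polynomial(xor3)
        assert p.coefficient("x") == p.coefficient("y") == p.coefficient("z") == 1
        assert p.coefficient("x", "y") == p.coefficient("x", "z") == \
            p.coefficient("y", "z") == -2
        assert p.coefficient("x", "y", "z") == 4
        assert p.constant == 0
        assert len(p.coeffs) == 7

    @pytest.mark.parametrize("gate,expected", [
        ("NOR", {(): 1, ("a",): -1, ("b",): -1, ("a", "b"): 1}),
        ("AND", {("a", "b"): 1}),
        ("OR", {("a",): 1, ("b",): 1, ("a", "b"): -1}),
        ("XOR", {("a",): 1, ("b",): 1, ("a", "b"): -2}),
        ("NOT", {(): 1, ("a",): -1}),
        ("NAND", {(): 1, ("a", "b"): -1}),
        ("XNOR", {(): 1, ("a",): -1, ("b",): -1, ("a", "b"): 2}),
    ])
    def test_gate_polynomials(self, gate, expected):
        p = cs.truth_table_to_polynomial(cs.gate_library(gate))
        assert p.coeffs == {frozenset(k): v for k, v in expected.items()}

    def test_unknown_gate(self):
        with pytest.raises(UnknownGateError):
            cs.gate_library("XNOR3")

    def test_vertex_inverse_examples(self):
        nor = MultilinearPolynomial.from_text("1 - a - b + a*b")
        assert cs.polynomial_to_truth_table(nor).outputs == (1, 0, 0, 0)
        both = MultilinearPolynomial.from_text("a*b")
        assert cs.polynomial_to_truth_table(both).outputs == (0, 0, 0, 1)

    def test_non_boolean_vertex_rejected(self):
        with pytest.raises(NotBooleanError):
            cs.polynomial_to_truth_table(MultilinearPolynomial({frozenset(): 0.5}))
        with pytest.raises(NotBooleanError):
            cs.polynomial_to_truth_table(
                MultilinearPolynomial({frozenset({"a"}): 0.5}))

    def test_round_trip_exhaustive_up_to_three_inputs(self):
        for n in (1, 2, 3):
            names = tuple(f"x{i}" for i in range(n))
            for bits in itertools.product((0, 1), repeat=2**n):
                if not any(bits):
                    continue  # all-zero polynomial has no variables to invert
                tt = cs.TruthTable(names, bits)
                back = cs.polynomial_to_truth_table(
                    cs.truth_table_to_polynomial(tt), name=tt.name)
                assert back.outputs == tt.outputs

    def test_round_trip_randomized_four_inputs(self):
        for seed in range(100):
            tt = cs.random_table(4, seed=seed)
            if not any(tt.outputs):
                continue
            back = cs.polynomial_to_truth_table(
                cs.truth_table_to_polynomial(tt), name=tt.name)
            assert back.outputs == tt.outputs

    def test_text_round_trip(self, xor3):
        p = cs.truth_table_to_polynomial(xor3)
        text = p.to_text()
        assert text == "x + y + z - 2*x*y - 2*x*z - 2*y*z + 4*x*y*z"
        assert MultilinearPolynomial.from_text(text).coeffs == p.coeffs

    def test_non_multilinear_text_rejected(self):
        with pytest.raises(ConfigurationError):
            MultilinearPolynomial.from_text("a**2 + b")


class TestCsvIO:
    def test_round_trip(self, xor3):
        buf = io.StringIO()
        cs.write_table_csv(xor3, buf)
        back = table_from_csv_text(buf.getvalue())
        assert back == xor3

    def test_row_order_enforced_with_line_number(self):
        text = "a,b,f\n0,0,1\n1,0,0\n0,1,0\n1,1,0\n"
        with pytest.raises(TableFormatError, match="line 3.*canonical"):
            table_from_csv_text(text)

    def test_non_bit_cell_reported(self):
        text = "a,f\n0,1\n1,2\n"
        with pytest.raises(TableFormatError, match="line 3"):
            table_from_csv_text(text)

    def test_wrong_row_count(self):
        with pytest.raises(TableFormatError, match="expected 4 data rows"):
            table_from_csv_text("a,b,f\n0,0,1\n")
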