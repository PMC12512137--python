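import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canalkit.boolean_core import all_nodes, random_node
from canalkit.prime_implicants import one_symbol_schemata
from canalkit.two_symbol import (
    TwoSymbolSchema,
    brute_force_two_symbol,
    compress_two_symbol,
    expand_two_symbol,
    minimal_cover,
)


def expansion_family(schemata):
    return {t.expand() for t in schemata}


class TestExpansion:
    def test_or2_schema_expands_to_both_implicants(self):
        t = TwoSymbolSchema(base="1#", groups=((0, 1),))
        assert expand_two_symbol(t) == {"1#", "#1"}

    def test_five_input_two_group_expansion(self):
        t = TwoSymbolSchema(base="#1001", groups=((0, 2), (3, 4)))
        assert expand_two_symbol(t) == {"#1001", "01#01", "#1010", "01#10"}

    def test_no_groups_expands_to_base(self):
        assert expand_two_symbol(TwoSymbolSchema(base="00")) == {"00"}

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            TwoSymbolSchema(base="10#", groups=((0, 1), (1, 2)))

    def test_trivial_group_rejected(self):
        with pytest.raises(ValueError, match="faithful"):
            TwoSymbolSchema(base="00", groups=((0, 1),))


class TestCompressionWorkedExamples:
    def test_or2_compresses_to_single_grouped_schema(self):
        (t,) = compress_two_symbol({"1#", "#1"}, "1")
        assert t.base == "1#" and t.groups == ((0, 1),)

    def test_or3_single_group_of_all_positions(self):
        (t,) = compress_two_symbol({"1##", "#1#", "##1"}, "1")
        assert t.groups == ((0, 1, 2),)

    def test_repeated_symbol_group(self):
        (t,) = compress_two_symbol({"11#", "1#1", "#11"}, "1")
        assert t.groups == ((0, 1, 2),)

    def test_fully_repeated_schema_gets_no_groups(self):
        (t,) = compress_two_symbol({"00"}, "0")
        assert t.base == "00" and t.groups == ()

    def test_five_input_partial_symmetries(self):
        (t,) = compress_two_symbol({"#1001", "#1010", "01#01", "01#10"}, "1")
        assert t.groups == ((0, 2), (3, 4))
        assert t.expand() == {"#1001", "#1010", "01#01", "01#10"}

    def test_singleton_input_returns_groupless_schema(self):
        (t,) = compress_two_symbol({"10#"})
        assert t.base == "10#" and t.groups == ()

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            compress_two_symbol({"1#", "1##"})

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            compress_two_symbol(set())


class TestContract:
    """Coverage, validity, faithfulness and determinism of the compression."""

    def _check(self, S):
        result = compress_two_symbol(S)
        union = set()
        for t in result:
            exp = t.expand()
            assert exp <= S  # validity
            union |= exp
            for g in t.groups:
                assert len({t.base[p] for p in g}) >= 2  # faithfulness
        assert union == S  # exact coverage

    def test_contract_on_random_k4_functions(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            node = random_node(4, rng.uniform(), rng)
            for v in "01":
                pis = one_symbol_schemata(node, v)
                if pis:
                    self._check(set(pis))

    def test_deterministic_output_order(self):
        S = {"1#0", "#10", "01#", "0#1", "10#"}
        assert compress_two_symbol(S) == compress_two_symbol(frozenset(S))

    def test_faithfulness_regression_on_repeated_symbols(self):
        # {00} admits only the trivial swap; no group may be emitted
        (t,) = compress_two_symbol({"00"})
        assert t.groups == ()


class TestOracleEquivalence:
    def test_all_k3_functions_match_brute_force(self):
        for node in all_nodes(3):
            for v in "01":
                pis = one_symbol_schemata(node, v)
                if not pis:
                    continue
                fast = compress_two_symbol(pis, v)
                slow = brute_force_two_symbol(pis, v)
                assert expansion_family(fast) == expansion_family(slow)
                assert fast == slow  # canonical forms agree too

    def test_sampled_k5_functions_match_brute_force(self):
        rng = np.random.default_rng(31)
        for _ in range(60):
            node = random_node(5, rng.uniform(), rng)
            for v in "01":
                pis = one_symbol_schemata(node, v)
                if not pis:
                    continue
                assert expansion_family(
                    compress_two_symbol(pis, v)
                ) == expansion_family(brute_force_two_symbol(pis, v))

    def test_brute_force_guard(self):
        with pytest.raises(ValueError, match="guard"):
            brute_force_two_symbol({"0" * 7 + "1"})


class TestAlphabetGenerality:
    def test_three_symbol_alphabet_full_symmetry(self):
        S = {"12#", "21#", "1#2", "2#1", "#12", "#21"}
        (t,) = compress_two_symbol(S)
        assert t.groups == ((0, 1, 2),)
        assert expansion_family([t]) == expansion_family(brute_force_two_symbol(S))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    perm=st.permutations(list(range(4))),
)
def test_permutation_invariance(seed, perm):
    """Relabeling input positions maps the output schemata accordingly."""
    rng = np.random.default_rng(seed)
    node = random_node(4, rng.uniform(), rng)
    for v in "01":
        pis = one_symbol_schemata(node, v)
        if not pis:
            continue

        def apply(s):
            return "".join(s[perm[i]] for i in range(4))

        direct = expansion_family(compress_two_symbol({apply(s) for s in pis}))
        mapped = {
            frozenset(apply(s) for s in exp)
            for exp in expansion_family(compress_two_symbol(pis))
        }
        assert direct == mapped


class TestMinimalCover:
    def test_cover_still_covers_target(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            node = random_node(4, rng.uniform(), rng)
            pis = one_symbol_schemata(node, "1")
            if not pis:
                continue
            maximal = compress_two_symbol(pis, "1")
            cover = minimal_cover(maximal, pis)
            assert set().union(*(t.expand() for t in cover)) == pis
            assert len(cover) <= len(maximal)
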