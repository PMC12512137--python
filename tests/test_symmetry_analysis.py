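import json
from fractions import Fraction

import numpy as np
import pytest

from canalkit.boolean_core import bias, node_from_outputs
from canalkit.symmetry_analysis import (
    EnsembleSpec,
    classification_fractions,
    generate_ensemble,
    null_comparison,
    run_null_analysis,
    summarize_distributions,
)


def threshold_node(k, tau, name="t"):
    outs = [
        "1" if format(r, f"0{k}b").count("1") >= tau else "0" for r in range(2**k)
    ]
    return node_from_outputs(k, outs, name=name)


def chain_node(k, neg_pattern, name="c"):
    """Nested alternating AND/OR chain; asymmetric by construction."""

    def f(bits):
        val = bits[-1] ^ neg_pattern[-1]
        for i in range(k - 2, -1, -1):
            b = bits[i] ^ neg_pattern[i]
            val = (b or val) if i % 2 == 0 else (b and val)
        return val

    outs = [
        "1" if f([int(c) for c in format(r, f"0{k}b")]) else "0"
        for r in range(2**k)
    ]
    return node_from_outputs(k, outs, name=name)


class TestEnsembleGeneration:
    def test_sizes_and_lut_length(self):
        nodes = generate_ensemble(EnsembleSpec(n_functions=25, k=5, seed=0))
        assert len(nodes) == 25 and all(len(n.outputs) == 32 for n in nodes)

    def test_fixed_rho_one_gives_constant(self):
        (node,) = generate_ensemble(EnsembleSpec(n_functions=1, k=2, rho=1.0, seed=0))
        assert node.outputs == ("1", "1", "1", "1")

    def test_identical_specs_identical_ensembles(self):
        spec = EnsembleSpec(n_functions=10, k=4, seed=42)
        assert generate_ensemble(spec) == generate_ensemble(spec)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            EnsembleSpec(n_functions=0, k=3)
        with pytest.raises(ValueError):
            EnsembleSpec(n_functions=1, k=3, rho="gaussian")


class TestNullComparison:
    def test_constant_node_all_shuffles_equal(self):
        node = node_from_outputs(3, "1" * 8)
        c = null_comparison(node, seed=1)
        assert set(c.classify()) == {"equal"}

    def test_shuffles_preserve_degree_and_bias_exactly(self):
        rng = np.random.default_rng(12)
        nodes = generate_ensemble(EnsembleSpec(n_functions=10, k=4, seed=12))
        for node in nodes:
            c = null_comparison(node, seed=rng)
            assert c.k == node.k and c.rho == bias(node)

    def test_maximally_symmetric_or5_never_increases(self):
        or5 = threshold_node(5, 1, "OR5")
        c = null_comparison(or5, n_shuffles=200, seed=7)
        assert "increased" not in c.classify()

    def test_fractions_sum_to_one(self):
        nodes = generate_ensemble(EnsembleSpec(n_functions=8, k=4, seed=3))
        comparisons = [null_comparison(n, seed=i) for i, n in enumerate(nodes)]
        fr = classification_fractions(comparisons)
        assert sum(fr.values()) == pytest.approx(1.0)

    def test_values_are_exact_rationals(self):
        node = threshold_node(4, 2)
        c = null_comparison(node, seed=0)
        assert isinstance(c.original, Fraction)
        assert all(isinstance(v, Fraction) for v in c.shuffled)


class TestDistributionSummary:
    def test_identical_samples_ks_zero(self):
        s = summarize_distributions([0.0, 1.0], [0.0, 1.0])
        assert s.ks_statistic == 0.0 and s.ks_pvalue == 1.0
        assert s.median_original == s.median_null

    def test_iqr_linear_interpolation_frozen(self):
        # type-7 quantiles of [1,2,3,4]: q25=1.75, q75=3.25 -> IQR=1.5
        s = summarize_distributions([1.0, 2.0, 3.0, 4.0], [1.0])
        assert s.iqr_original == pytest.approx(1.5)
        assert s.percentiles_original[75.0] == pytest.approx(3.25)

    def test_percentiles_monotone(self):
        rng = np.random.default_rng(0)
        s = summarize_distributions(rng.random(50), rng.random(50))
        q = [s.percentiles_original[p] for p in (25.0, 50.0, 75.0)]
        assert q == sorted(q)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_distributions([], [1.0])


class TestPipeline:
    def test_reproducible_byte_for_byte(self):
        nodes = generate_ensemble(EnsembleSpec(n_functions=6, k=4, seed=5))

        def run():
            table, summary, fractions = run_null_analysis(nodes, seed=5)
            return json.dumps(
                {
                    "table": table.to_dict("records"),
                    "fractions": fractions,
                    "median": summary.median_original,
                    "ks": summary.ks_statistic,
                },
                sort_keys=True,
            )

        assert run() == run()

    def test_extreme_symmetry_ensemble_wider_than_null(self):
        """Functions at both symmetry extremes spread wider than their
        degree-and-bias matched shuffles."""
        rng = np.random.default_rng(7)
        nodes = [threshold_node(4, tau, f"thr{i}") for i, tau in enumerate([1, 2, 3, 4] * 4)]
        nodes += [
            chain_node(4, tuple(rng.integers(0, 2, 4)), f"chain{i}")
            for i in range(16)
        ]
        _, summary, _ = run_null_analysis(nodes, seed=3)
        assert summary.iqr_original > summary.iqr_null
        assert summary.ks_pvalue < 0.01

    def test_pooling_modes(self):
        nodes = generate_ensemble(EnsembleSpec(n_functions=5, k=3, seed=9))
        _, pooled, _ = run_null_analysis(nodes, seed=2, pooling="pooled")
        _, by_mean, _ = run_null_analysis(nodes, seed=2, pooling="mean")
        assert pooled.median_original == by_mean.median_original
        with pytest.raises(ValueError):
            run_null_analysis(nodes, seed=2, pooling="other")
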