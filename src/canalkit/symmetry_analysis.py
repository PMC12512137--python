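"""Symmetry distributions versus degree-and-bias matched null models.

The pipeline: generate (or load) an ensemble of Boolean functions,
compute each function's normalized input symmetry ``k_s / k``, build a
matched null by shuffling each function's output column (12 shuffles by
default — a uniform permutation preserves in-degree and bias exactly),
classify each shuffle as increasing / leaving equal / decreasing the
symmetry, and compare the original and null distributions (median, IQR,
percentiles, two-sample Kolmogorov-Smirnov test).

Classification uses exact rational arithmetic: under the default
aggregation ``k_s / k`` is a ratio of integers, so "equal" means equal,
with no floating-point tolerance.
"""

from __future__ import annotations

import dataclasses
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .boolean_core import BooleanNode, random_node, shuffle_outputs
from .measures import normalized_input_symmetry

__all__ = [
    "EnsembleSpec",
    "ShuffleComparison",
    "DistributionSummary",
    "generate_ensemble",
    "null_comparison",
    "comparison_table",
    "classification_fractions",
    "summarize_distributions",
    "run_null_analysis",
]

DEFAULT_N_SHUFFLES = 12


@dataclasses.dataclass(frozen=True)
class EnsembleSpec:
    """A random-function ensemble: ``n_functions`` draws with in-degree ``k``.

    ``rho`` is either a number (fixed bias for every function) or the
    string ``"uniform"``: each function first draws its bias uniformly
    from [0, 1], then its outputs i.i.d. Bernoulli at that bias.
    """

    n_functions: int
    k: int
    rho: float | str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_functions < 1:
            raise ValueError("n_functions must be >= 1")
        if isinstance(self.rho, str) and self.rho != "uniform":
            raise ValueError(f"rho must be a number or 'uniform', got {self.rho!r}")


@dataclasses.dataclass(frozen=True)
class ShuffleComparison:
    """One function's symmetry against its shuffled null rules."""

    name: str
    k: int
    rho: float
    original: Fraction
    shuffled: tuple[Fraction, ...]

    def classify(self) -> tuple[str, ...]:
        """Per shuffle: ``increased`` / ``equal`` / ``decreased`` (exact)."""
        return tuple(
            "increased" if s > self.original
            else "decreased" if s < self.original
            else "equal"
            for s in self.shuffled
        )


@dataclasses.dataclass(frozen=True)
class DistributionSummary:
    """Original-vs-null distribution comparison of ``k_s / k`` values."""

    median_original: float
    median_null: float
    iqr_original: float
    iqr_null: float
    percentiles_original: dict[float, float]
    percentiles_null: dict[float, float]
    ks_statistic: float
    ks_pvalue: float


def generate_ensemble(spec: EnsembleSpec) -> list[BooleanNode]:
    """Seeded, reproducible ensemble of random Boolean functions."""
    rng = np.random.default_rng(spec.seed)
    nodes = []
    for i in range(spec.n_functions):
        rho = rng.uniform() if spec.rho == "uniform" else float(spec.rho)
        nodes.append(random_node(spec.k, rho, rng, name=f"random{i}"))
    return nodes


def null_comparison(
    node: BooleanNode,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int | np.random.Generator = 0,
    **ks_kwargs,
) -> ShuffleComparison:
    """Symmetry of one function against its shuffled-output null rules."""
    original = normalized_input_symmetry(node, exact=True, **ks_kwargs)
    shuffled = tuple(
        normalized_input_symmetry(s, exact=True, **ks_kwargs)
        for s in shuffle_outputs(node, n_shuffles, seed)
    )
    return ShuffleComparison(
        name=node.name,
        k=node.k,
        rho=node.outputs.count("1") / len(node.outputs),
        original=Fraction(original),
        shuffled=shuffled,
    )


def comparison_table(comparisons: Sequence[ShuffleComparison]) -> pd.DataFrame:
    """Tidy table: one row per function per shuffle, with classification."""
    records = []
    for c in comparisons:
        for j, (value, label) in enumerate(zip(c.shuffled, c.classify())):
            records.append(
                {
                    "name": c.name,
                    "k": c.k,
                    "rho": c.rho,
                    "ks_over_k": float(c.original),
                    "shuffle": j,
                    "ks_over_k_shuffled": float(value),
                    "classification": label,
                }
            )
    return pd.DataFrame.from_records(records)


def classification_fractions(comparisons: Sequence[ShuffleComparison]) -> dict[str, float]:
    """Fractions of shuffles that increased / equalled / decreased symmetry."""
    labels = [lab for c in comparisons for lab in c.classify()]
    n = len(labels)
    return {
        key: labels.count(key) / n for key in ("increased", "equal", "decreased")
    }


def summarize_distributions(
    originals: Sequence[float],
    shuffled: Sequence[float],
    percentiles: Sequence[float] = (25.0, 50.0, 75.0),
) -> DistributionSummary:
    """Median, IQR, requested percentiles and two-sample KS comparison.

    Percentiles use linear interpolation (quantile type 7); the IQR is
    the 75th minus the 25th percentile.
    """
    orig = np.asarray(originals, dtype=float)
    null = np.asarray(shuffled, dtype=float)
    if orig.size == 0 or null.size == 0:
        raise ValueError("both value sets must be nonempty")

    def iqr(v: np.ndarray) -> float:
        lo, hi = np.percentile(v, [25.0, 75.0])
        return float(hi - lo)

    ks = stats.ks_2samp(orig, null, method="auto")
    return DistributionSummary(
        median_original=float(np.median(orig)),
        median_null=float(np.median(null)),
        iqr_original=iqr(orig),
        iqr_null=iqr(null),
        percentiles_original={p: float(np.percentile(orig, p)) for p in percentiles},
        percentiles_null={p: float(np.percentile(null, p)) for p in percentiles},
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
    )


def run_null_analysis(
    nodes: Sequence[BooleanNode],
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
    pooling: str = "pooled",
) -> tuple[pd.DataFrame, DistributionSummary, dict[str, float]]:
    """End-to-end shuffle-null pipeline for a set of functions.

    ``pooling`` controls the null sample entering the KS comparison:
    ``"pooled"`` uses every shuffle value, ``"mean"`` the per-function
    mean across shuffles.  Returns the tidy per-shuffle table, the
    distribution summary and the classification fractions.
    """
    if pooling not in ("pooled", "mean"):
        raise ValueError(f"unknown pooling {pooling!r}")
    rng = np.random.default_rng(seed)
    comparisons = [
        null_comparison(node, n_shuffles, rng) for node in nodes
    ]
    table = comparison_table(comparisons)
    originals = [float(c.original) for c in comparisons]
    if pooling == "pooled":
        null_values = [float(v) for c in comparisons for v in c.shuffled]
    else:
        null_values = [float(np.mean([float(v) for v in c.shuffled])) for c in comparisons]
    summary = summarize_distributions(originals, null_values)
    return table, summary, classification_fractions(comparisons)
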