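# Methods

## Background and scope

Boolean networks model biomolecular regulation as coupled automata: each
node carries a state in {0,1} and updates synchronously via a lookup
table (LUT) over its k inputs. *Canalization* — the buffering of input
fluctuations — shows up in these models as redundancy: some inputs
rarely matter (input redundancy), and some inputs are functionally
interchangeable (input symmetry). canalkit quantifies both exactly,
starting from schema redescription of the LUT, and propagates them to
network-level causal maps and a null-model analysis of symmetry
distributions.

## Conventions

- LUT row index `i` encodes the input configuration as the binary
  expansion of `i` with **input 0 as the most significant digit**
  (rows `00, 01, 10, 11` for k=2). Inputs and schema positions are
  0-based everywhere, including JSON serializations.
- Bias ρ is the fraction of LUT rows with output 1.
- Deterministic ordering of schemata uses symbol order `0 < 1 < #`
  (wildcard last).

## One-symbol schemata (prime implicants)

A one-symbol schema is a string over {0,1,#} covering the input
configurations obtained by filling wildcards; a prime implicant covers
only rows of one output value and cannot be widened. We enumerate **all**
prime implicants of the function and of its negation by Quine–McCluskey
pairwise merging, with no cover minimization: the symmetry stage needs
the complete set so that symmetric siblings (both `1#` and `#1` for the
2-input OR) are available. Constant functions yield the all-# schema for
the constant output and the empty set otherwise. Correctness (purity,
coverage, primality) is validated in the test suite against an
independent enumerator of all 3^k candidate schemata.

## Two-symbol schemata (exact symmetry compression)

A two-symbol schema is a base schema plus disjoint position groups whose
symbols may appear in any arrangement of their multiset; its expansion
is the set of one-symbol schemata reachable by rearranging each group
independently. Groups must be *faithful*: at least two distinct symbols,
so that some permutation actually changes the string (a group of
identical symbols encodes only the trivial action and is excluded — the
regression case is `{00}`, which compresses to itself with no groups).

`compress_two_symbol(S)` returns every **maximal** valid schema: the
expansion lies inside S, and is not strictly contained in the expansion
of any other valid schema; the union of expansions equals S exactly.
Distinct maximal schemata may overlap in coverage; a greedy
`minimal_cover` reduction (largest expansion first, lexicographic
tie-break) is provided for users who want a cover rather than the full
maximal family.

Algorithm. Permuting positions preserves the symbol multiset, so S is
first partitioned into multiset classes. For each base string, group
structures are enumerated by a canonical DFS over set partitions of the
positions (restricted-growth order; final singleton blocks are
ungrouped). Validity is monotone — shrinking a structure shrinks its
orbit — so any partial structure whose orbit already escapes the class
is pruned losslessly. Orbits are base-independent (any expansion member
regenerates the same expansion with the same blocks), which makes
re-basing sound: the canonical representative uses the lexicographically
smallest expansion member as base. When two structures generate the same
expansion, the one grouping more positions (then fewer groups, then
lexicographically smaller) is kept. Expansion-dominated candidates are
discarded at the end by pairwise subset checks.

`brute_force_two_symbol` is an intentionally independent oracle: blunt
enumeration of all set partitions per base, with orbits computed by
applying per-block *position permutations* (the group-action definition)
rather than multiset rearrangement. The two routes are cross-checked on
all 256 k=3 functions (both outputs) and 500 seeded random k=5
functions; the oracle carries tractability guards (k ≤ 6, |S| ≤ 64).

Nothing in the compression assumes Boolean symbols; sets over alphabets
such as {0,1,2,#} compress identically (multi-valued hook, exercised in
tests).

## Canalization measures

**Input redundancy / effective connectivity.** For each LUT row, the
covering prime implicants of the row's output are ranked by wildcard
count and a configurable bound selects among them: `min` (default,
fewest wildcards — the most conservative redundancy estimate), `max`
(most wildcards), or `mean` (midpoint of the two). k_r is the mean
selected wildcard count over all 2^k rows; k_e = k − k_r identically.
When several schemata achieve the bound their per-input wildcard
indicators are averaged, which removes order dependence and keeps the
effective graph consistent (below).

**Input symmetry.** For input i and two-symbol schema T, s_i(T) is the
size of the group of T containing i, or 1 if ungrouped. Schemata of both
output values contribute. The per-input aggregate is, by default, the
mean of s_i(T) weighted by the number of LUT rows T covers (its
expansion expanded to configurations, deduplicated); unweighted mean and
maximum aggregation are available. k_s is the mean over the k inputs and
k_s/k ∈ [0,1] its normalized form. Under the default aggregation all
quantities are ratios of integers, and the implementation carries them
as exact rationals (`fractions.Fraction`) when requested — the
shuffle-null classification relies on this for tolerance-free equality.
This operationalization ("average permutation-group size, aggregated by
input, weighted by coverage") is frozen by regression tests (e.g. the
3-input OR gives k_s = 11/4 = (3·7 + 1·1)/8); alternative formal
definitions could differ in weighting, which is why both choices are
configurable.

**Threshold extraction.** An output-1 two-symbol schema of an
equal-weight threshold function has exactly τ ON literals in its base
(group-invariant); `schema_threshold` counts them. The 3-input
disjunction yields τ=1, the 3-input majority τ=2, the 3-input
conjunction τ=3.

**Classifier flags.** `has_literal_wildcard_group` is true when some
group's symbols contain a wildcard together with a literal — the
signature of threshold-like, collectively redundant logic.
`has_zero_one_group` is true when some group contains both 0 and 1 —
the signature of XOR-like, non-monotone logic. Monotonicity (unateness)
is classified directly from the LUT by pointwise comparison of all
0→1 input flips.

## Macro-level maps

**Effective graph.** Edge j→i carries e_ij = 1 − r_ij, with r_ij the
mean probability (over rows of node i, under the same per-row schema
selection as k_r) that input j is a wildcard in the selected schema.
Consequently Σ_j e_ij = k_e(i) exactly, and e_ij = 0 iff j is
inessential. Edges with zero effectiveness are kept in the graph so the
structural wiring remains visible.

**Dynamics canalizing map (DCM).** One transition unit (t-unit) per
two-symbol schema per node per output. Ungrouped literal positions
become mandatory state-unit inputs; each group compiles to "at least
m_v of these inputs carry value v" for every literal v in the group's
symbol multiset — the set of enabling configurations of these
conditions equals the schema's expansion exactly (assign literals to
matching positions greedily). The unit's threshold τ is the number of
non-wildcard base positions. Fidelity is validated by exhaustively
checking, on every fixture network, that t-unit evaluation reproduces
the LUT update in all states — this behavioural check, not notational
identity with any particular drawing convention, is the correctness
criterion.

## Dynamics

Synchronous update only. Pinned-node simulation clamps the pinned value
*after* each step, so a pinned node's current value is still visible to
its targets during the step in which pinning begins. Exhaustive
attractor enumeration traverses the full state-transition graph (guard:
20 nodes) and reports exact basin sizes, which partition the state
space. Note the synchronous 3-node odd negation loop has two cyclic
attractors (the 000↔111 2-cycle and a 6-cycle) — a useful reminder
that synchronous cycles differ from their asynchronous counterparts.

Perturbation response: per-node sensitivity is the fraction of
(row, input) pairs where a single bit-flip changes the output; the
network-level Derrida step is the expected normalized Hamming distance
one synchronous step after a single-bit perturbation, exhaustive when
states × bits ≤ 2^16 and seeded Monte Carlo beyond.

## Ensembles and the shuffle null

`EnsembleSpec(n, k, rho, seed)` draws n random k-input functions;
`rho="uniform"` (default) first draws each function's bias uniformly
from [0,1] and then its outputs i.i.d. Bernoulli(ρ) — per-function bias
sampling is our reading of "bias ρ ∈ [0,1]" ensembles, chosen once and
flagged as a convention rather than asserted as the only one.

The null model for a function shuffles its output column (12 shuffles
by default) with a uniform random permutation, preserving k and ρ
*exactly* since the output multiset is untouched. Each shuffle is
classified as increasing / equalling / decreasing k_s/k by exact
rational comparison (tolerance 0 under the default aggregation; a
tolerance flag exists for floating-point aggregation modes).
Distribution comparison reports medians, IQRs and percentiles with
linear interpolation (quantile type 7 — stated because IQR values
depend on it) and a two-sample Kolmogorov–Smirnov test. Pooling all
shuffle values into the null sample is the default; per-function means
are available (`pooling="mean"`).

## What the synthetic ensembles do and do not show

The test ensembles emulate the statistical structure of curated
biological rule sets — a mix of highly symmetric threshold-like
functions and asymmetric nested-chain functions, against random
functions of matched degree and bias. They reproduce the qualitative
signature of curated corpora: a wider k_s/k spread in the originals
than in their shuffled nulls (extremes of symmetry and asymmetry are
over-represented relative to chance). They do not reproduce any
particular repository's numerical statistics: real model corpora have
heterogeneous in-degrees, correlated rules within a network, and
curation biases that no i.i.d. generator emulates. Passing tests
demonstrate correctness of the machinery and the direction of the
effect, not corpus-level magnitudes.

## Problem sizes and numerical choices

The exhaustive suites run all 256 k=3 functions wherever the check is
exhaustive; sampled suites use 500 seeded random k=5 functions for
compression-oracle equivalence and 2000 for prime-implicant
correctness — sizes chosen as the package's standard validation
battery. All randomness flows through explicit
`numpy.random.Generator` seeds; no global RNG state is used. Exact
integer/rational arithmetic is used for schema expansion, coverage
counts and symmetry classification; floating point enters only in
aggregate summaries (means, percentiles, KS statistics).

## Known limitations

- Prime-implicant merging and the measures assume Boolean alphabets;
  only the two-symbol compression layer is alphabet-generic.
- Asynchronous and stochastic update schemes are out of scope.
- The brute-force oracle is exponential (Bell numbers × orbit checks)
  and guarded to k ≤ 6; the production compression has no such guard
  but is itself exponential in the worst case — practical for the
  in-degrees typical of curated Boolean models (k ≲ 10).
- Control-pathway search over the DCM is not implemented; pinned-node
  simulation is the only intervention primitive.
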