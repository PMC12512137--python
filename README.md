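# canalkit

Exact quantification of **canalization** in Boolean automata networks.

Biomolecular networks function in noisy environments by buffering input
fluctuations. In Boolean network models this buffering appears as two
kinds of redundancy in each node's update rule f: {0,1}^k → {0,1}:

- **input redundancy** — some inputs rarely matter once others are set
  (e.g. either input of an OR gate suffices);
- **input symmetry** — some inputs are functionally interchangeable,
  as among transcription factors that bind the same promoter.

canalkit measures both, exactly, for automata given as lookup tables
(LUTs) or as logical rule files, and for whole networks.

## What it computes

Starting from a rule's LUT:

1. **One-symbol schemata** — all prime implicants of f and of ¬f,
   strings over {0,1,#} (# = "don't care"). The 2-input OR compresses
   to `{1#, #1} ↦ 1` and `{00} ↦ 0`.
2. **Two-symbol schemata** — maximal *faithful permutation symmetries*
   among inputs: disjoint position groups (marked °, ^, …) whose
   symbols may permute without changing the output. `{1#, #1}`
   compresses further to `1°#°`. The compression is exact: an
   exhaustive, pruned search over group structures, cross-validated
   against an independent brute-force oracle.
3. **Canalization measures** — input redundancy k_r (mean wildcards in
   the per-row schema redescription), effective connectivity
   k_e = k − k_r, input symmetry k_s (mean permutation-group size per
   input, weighted by schema coverage) and its normalized form k_s/k.
4. **Macro-level maps** — the *effective graph* (edges weighted by
   effectiveness e_ij, with Σ_j e_ij = k_e) and the *dynamics
   canalizing map* (an exact threshold-network form whose transition
   units reproduce the synchronous dynamics).
5. **Dynamics** — synchronous trajectories, exhaustive attractors and
   basin sizes, pinned-node simulation, sensitivity and Derrida-step
   perturbation response.
6. **Null-model analysis** — symmetry distributions of a rule set
   against degree-and-bias matched nulls built by shuffling each LUT's
   output column (12 shuffles by default, preserving k and bias ρ
   exactly), with exact increased/equal/decreased classification,
   medians, IQRs and a two-sample Kolmogorov–Smirnov comparison.

## Worked example

The 3-input majority rule (x1∧x2)∨(x2∧x3)∨(x1∧x3) — a threshold
function with τ = 2:

```python
import canalkit as ck

node = ck.node_from_outputs(3, "00010111", name="MAJ3")

for v, schemata in ck.two_symbol_schemata(node).items():
    for t in schemata:
        print(t)
# 0°0°#°↦0
# 1°1°#°↦1

print(ck.schema_threshold(ck.two_symbol_schemata(node)["1"][0]))  # 2
print(ck.summarize_node(node))
# CanalizationSummary(name='MAJ3', k=3, k_r=1.0, k_e=2.0, k_s=3.0,
#   ks_over_k=1.0, has_literal_wildcard_group=True,
#   has_zero_one_group=False, is_unate=True)
```

Reading: any two ON inputs activate the node and any two OFF inputs
deactivate it, with all three inputs interchangeable (one group of size
3 in each schema, hence k_s/k = 1). On average one input per
configuration is redundant (k_r = 1), so the rule effectively depends
on k_e = 2 inputs — the threshold. The schema base `11#` contains two
ON literals, recovering τ = 2.

The same analyses run from the shell on LUT (`.lut`) or
"targets, factors" rule files:

```sh
canalkit schemata model.txt --two-symbol
canalkit measures model.txt --node MAJ3
canalkit effective-graph model.txt -o eff.dot
canalkit dynamics model.txt --attractors
canalkit --seed 1 ensemble --n 100 --k 5 --csv-out shuffles.csv
```

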