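# ontosim

Graph-based semantic similarity for Gene Ontology terms and gene products:
weighted-contribution measures built on the lowest common ancestor (LCA) and
the highest common descendant (HCD), Best-Match-Average (BMA) gene
similarity, and a clustering evaluation harness for benchmarking measures
against gold-standard functional classes (e.g. top-level Enzyme Commission
classes).

## The problem

Gene products annotated with GO terms are routinely compared by *function*
rather than sequence or structure. The GO is three rooted DAGs (molecular
function, biological process, cellular component) whose terms are linked by
typed relationships (`is_a`, `part_of`, the `regulates` family). A good
term-pair similarity should (i) respect relationship types, (ii) not be
inflated by the root — direct children of a root are not similar — and
(iii) reward *common descendants*, which witness shared specific function
below the compared terms. Classical measures miss at least one of these:
information-content measures (Resnik, Lin) depend on a shifting annotation
corpus, edge-counting measures (Wu–Palmer) treat all edges alike, and
structural measures that count the root (Wang) score *deeper* sibling pairs
as *less* similar.

## The measures

Every edge gets a weight by relationship class (defaults: `is_a` 0.8,
`part_of` 0.6, `regulates` 0.7). The contribution of an ancestor *t* to an
anchor term *A* is the maximum over connecting paths of the product of edge
weights, with S_A(A) = 1 and S_A(root) = 0:

    S_A(t) = max { W_e · S_A(t') : t' a child of t in A's upward DAG }

- **baseline** — shared upward contributions over total semantic values:
  `Σ_{t∈T_A∩T_B} (S_A(t)+S_B(t)) / (SV(A)+SV(B))` with `SV = Σ_t S(t)`.
  With the root contributing normally instead of 0 this is exactly
  **wang** (Wang's structural-IC measure).
- **baseline_lca** — upward similarity anchored at the LCA:
  `2·SV(LCA) / (SV(A)+SV(B))`, where SV is the *max-path* semantic value
  (best single root-reaching path) so multiple noisy root paths don't
  accumulate.
- downward similarity — shared contributions of common descendants, both
  terms truncated at the depth of the highest common descendant; zero when
  no common descendant exists.
- **gontosim** — `U · Sim_LCA + L · Sim_Desc` with U = L = 0.5;
  **baseline_desc** mixes the plain baseline with the downward component.
- **tanimoto_baseline / tanimoto_gontosim** — weighted-set Tanimoto
  (`Σ min / Σ max`) over the contribution maps.
- **resnik, lin, wu_palmer** — corpus- and depth-based comparison baselines.

Gene similarity is Best-Match-Average over the genes' term sets, and the
evaluation harness clusters the gene–gene similarity matrix (complete
linkage on `1 − sim`) and scores purity, adjusted Rand index,
Fowlkes–Mallows, NMI, homogeneity, completeness and V-measure under an
equal-samples-per-class, repeated-sampling protocol.

## Worked example

`python examples/term_similarity.py` scores the toy ontology's sibling pair
(A, B) — two leaves under one intermediate, with a shared child D:

```
measure             upward  downward   total
baseline            0.4444    0.0000  0.4444
baseline_lca        0.5556    0.0000  0.5556
gontosim            0.5556    0.4444  0.5000
wang                0.5902    0.0000  0.5902
```

The baseline shares only the intermediate C1 (0.8 from each side) out of a
total semantic value of 1.8 + 1.8, hence 1.6/3.6 = 0.4444. The LCA-anchored
score is 2·SV(C1)/(SV(A)+SV(B)) = 2/3.6 = 0.5556. The downward component
through D is again 1.6/3.6, and gontosim averages the two: 0.5. Wang's
variant counts the root (0.64 from each side), inflating the score to
0.5902.

`python examples/gene_similarity.py` lifts this to genes
(`sim(enzyme1, enzyme2) = (1 + sim(B,A) + 1)/3 = 0.8333`), and
`python examples/clustering_evaluation.py` runs the full pipeline on a
six-class synthetic corpus with 20% annotation noise (purity 0.92 ± 0.02
across 5 sampling repeats).

A thin CLI wraps the same API: `ontosim term-sim`, `ontosim gene-sim`,
`ontosim cluster-eval`, `ontosim make-fixtures` (see `ontosim --help`).

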