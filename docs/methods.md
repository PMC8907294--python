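# Methods

## Ontology model

An ontology is loaded (via `obonet`) into a typed DAG restricted to the
relationship classes that carry semantic weight here: `is_a`, `part_of`, and
the `regulates` family (`positively_regulates` / `negatively_regulates` are
folded into `regulates` for weighting, since the weight table has a single
regulates entry). `occurs_in` and `has_part` are ignored. Edges crossing
namespaces are dropped — similarity is defined per aspect (MF/BP/CC) and a
pair of terms from different aspects has no common ancestor by construction.
Obsolete terms are parsed but excluded from traversal; `alt_id`s resolve to
their canonical term, and lookups of unresolvable or obsolete IDs fail
loudly rather than silently returning zeros. Validation enforces a single
root per namespace, acyclicity, and at least one within-namespace parent for
every non-root term.

Two depth notions coexist: `depth_longest` (longest root-to-term path),
which drives contribution truncation, LCA/HCD selection and the "deeper
means more specific" ordering; and `depth_shortest`, used only by the
Wu–Palmer comparison measure.

## Contributions and semantic values

Each edge carries a weight in (0, 1] by relationship class — defaults 0.8
(`is_a`), 0.6 (`part_of`), 0.7 (`regulates`). The contribution of an
ancestor `t` to an anchor `A` is the maximum over `A→t` paths of the product
of edge weights, computed by dynamic programming in depth order (a parent is
always strictly shallower than its child, so longest-path depth is a valid
topological key). In root-zeroed mode the namespace root is forced to 0;
with the root contributing normally the shared-contribution ratio reproduces
Wang's measure exactly, which the tests pin against an independent recursive
implementation.

Two aggregate semantic values are used:

- *sum*: `SV(A) = Σ_t S_A(t)` over the whole upward (or truncated downward)
  map;
- *max-path*: the best single root-reaching path, where each node on a path
  contributes the edge-weight product accumulated **along that particular
  path** (root 0). This path-local reading matches the measure's worked
  examples (on the diamond graph with one shortcut the best path scores
  1 + 0.8 + 0.64 + 0 = 2.44); the alternative reading that re-uses the
  globally maximal contributions on the chosen path would give 2.6 there.
  The implementation sweeps a Pareto front of (path-sum, path-product)
  states per node instead of enumerating paths, and is checked against full
  enumeration to 1e−12.

Max-path SV never exceeds sum SV (a path's local contributions are bounded
by the global maxima of a subset of terms), which the property tests assert.

## Term-pair measures

- `sim_baseline`: shared upward contributions over `SV(A)+SV(B)` (sum-mode
  SV, root zeroed). `sim_wang` is the same ratio without root-zeroing.
- `sim_lca` / `baseline_lca`: `2·SV_maxpath(LCA) / (SV_maxpath(A) +
  SV_maxpath(B))`. The LCA is the deepest (longest-path depth) common
  ancestor, each term counting as its own ancestor; ties break by larger
  max-path SV, then lexicographically smallest ID. The SV tie-break is an
  interpretation — no rule is published for tied depths — chosen so the
  tie-break follows the measure's own notion of importance, and made
  deterministic by the final lexicographic step.
- `sim_desc`: the highest common descendant (HCD) is the shallowest *strict*
  common descendant (a term does not count as its own descendant; ties break
  lexicographically). It fixes per-term truncation depths
  `depth(HCD) − depth(X)`, applied separately to each term, so asymmetric
  cuts are possible. Shared truncated downward contributions are divided by
  the two truncated downward SVs, anchors included (each anchor contributes
  its own 1, keeping the score below 1 for distinct terms). No common
  descendant ⇒ 0. All common descendants within the cut are summed — the
  HCD only sets the cut depth.
- `sim_gontosim = U·sim_lca + L·sim_desc` (defaults U = L = 0.5);
  `sim_baseline_desc` mixes the plain baseline instead of the LCA component
  (U = 0.7, L = 0.3 is the documented alternative mix).
- **Identity convention**: identical terms score exactly 1. For a leaf pair
  (a, a) the literal mixture would give 0.5 (no common descendant), which
  violates the identity axiom every other registered measure satisfies and
  would poison BMA gene similarity (a gene would not be maximally similar to
  itself). `literal_mixture=True` restores the literal behavior for anyone who
  wants it.
- `sim_tanimoto`: weighted-set Tanimoto `Σ_t min(S_A,S_B) / Σ_t max(S_A,S_B)`
  over the upward maps (baseline variant) or mixed with a Tanimoto over the
  HCD-truncated downward maps via U/L (combined variant). The exact
  Tanimoto form is not published; the min/max weighted-set form is chosen
  because it preserves identity and bounds.
- `wu_palmer`: the classic edge-counting form `2·N3 / (N1 + N2 + 2·N3)`
  (N3 = shortest-path depth of the common ancestor, N1/N2 = shortest
  distances from each term to it, maximized over common ancestors). On a
  tree this equals `2·depth(LCA)/(depth(A)+depth(B))`; the ratio form was
  not used directly because on DAGs with shortcut edges it exceeds 1.
- `resnik` / `lin`: IC from annotation frequency under the true-path rule —
  each (gene, term) annotation increments the term and its full ancestor
  closure; `P(T) = count(T)/count(root)`, `IC = −ln P`. Resnik returns the
  raw IC of the most informative common ancestor (unbounded above, excluded
  from the [0,1] axiom checks); Lin normalizes by the terms' own IC and is
  defined as 0 when the denominator vanishes. Both traverse the same typed
  closure as every other measure (the cited originals use `is_a` only);
  this keeps one traversal semantics across the package and is a documented
  divergence.

Degenerate inputs: ratios with zero denominators (e.g. both terms are the
root, or the LCA is the root under root-zeroing) return 1 for identical
terms and 0 otherwise.

## Gene similarity and evaluation

Gene similarity is Best-Match-Average: each term is scored against its best
match in the other gene's set and the matched scores from both directions
are averaged over `m + n`. BMA is the only set combination implemented.
Matrix construction memoizes term-pair totals keyed on the unordered pair
(measure and weights fixed per build); the cache is observationally
transparent, which a test checks by comparing cached and uncached matrices.

Clustering uses scikit-learn's agglomerative clustering on the precomputed
distance `1 − similarity` with complete linkage (the distance transform is a
design choice; similarities are already in [0, 1]). Purity is computed from
the contingency table; ARI, Fowlkes–Mallows, NMI (arithmetic
normalization — the concrete "mutual-information-based score"),
homogeneity, completeness and V-measure come from scikit-learn. The
equal-sampling protocol draws the same number of genes per class without
replacement, one seeded generator driving all repeats, and reports
mean ± sd per metric over the repeats (default 10).

## Synthetic data

`make_random_dag` produces seeded layered DAGs (edges only toward strictly
shallower layers, every node parented, mixed edge types) used for
property-based and oracle testing. `make_class_ontology` +
`make_class_annotations` emulate an enzyme-classification corpus: six
disjoint branches under the root, 20 genes per class, 3 terms per gene
sampled from the class branch, and annotation noise modeled as uniform term
replacement (probability `noise`) — the simplest corruption that degrades
measures relying on shared shallow ancestors, the failure mode attributed
to root-counting measures on electronically inferred annotations.

What the generator does *not* model: realistic GO topology (term fan-in,
depth distribution, cross-branch sharing between functional classes),
annotation bias, or evidence-code structure. Passing the synthetic
clustering tests therefore shows that the pipeline is correct and that the
combined measure degrades no faster than the baseline under uniform noise —
not that real-corpus purity values will be reproduced. The published
clustering scores depend on a specific Swiss-Prot/QuickGO snapshot and are
out of scope here; worked term-pair values on the real ontology are tested
whenever a local `go-basic.obo` (release 2020-01-01) is available.

## Numerical choices and problem sizes

All oracle comparisons use an absolute tolerance of 1e−12; depths and set
queries are exact. The acceptance script and tests run on 200 random DAGs
of ≤ 31 nodes (exhaustive path enumeration stays cheap at that size), a
20-DAG ≤ 12-node suite checked on *all* term pairs and all measures, and a
120-gene synthetic corpus (6 × 20) for the clustering pipeline — sizes
chosen so the whole suite completes in seconds while the enumeration
oracles remain exact. Seeds are explicit everywhere: graph generators and
annotation generators are pure functions of their seed, and the evaluation
protocol derives all repeats from one `numpy` generator.

## Known limitations

- The max-path semantic value interpretation (path-local products) is one
  of two defensible readings of the published definition; the choice is
  pinned by worked examples and documented above.
- Whether identical leaf terms should score 0.5 or 1 under the combined
  measure cannot be settled from the published description; the identity
  convention is the default here.
- IC estimation counts annotation-level frequencies; gene-level counting
  (each gene counts once per term) would give slightly different tables on
  corpora with many multi-annotated genes.
- QuickGO fetching is implemented against the public REST schema but is
  exercised only with canned pages in tests (no network in CI).
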