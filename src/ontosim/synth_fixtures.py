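"""Synthetic ontologies, annotation corpora and exhaustive-enumeration oracles.

Everything here exists so the rest of the package is testable offline:

* a deterministic 5/6-term toy ontology realizing the worked examples used
  throughout the docs and tests;
* seeded random layered DAGs with mixed relationship types;
* class-structured annotation corpora emulating an enzyme-classification
  setting — each class is anchored at its own branch of the ontology and
  genes sample terms from their branch, optionally corrupted by uniform
  term replacement (a crude stand-in for noisy electronic annotation);
* brute-force oracles for contributions, semantic values, LCA/HCD sets and
  depths that enumerate every path explicitly and share no traversal code
  with the main implementations (exponential cost, fine on tiny graphs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation_io import GeneAnnotationSet
from .obo_graph import OntologyGraph, RelationType, Term
from .term_semantics import DEFAULT_WEIGHTS, WeightConfig

__all__ = [
    "TOY",
    "SyntheticOntologySpec",
    "make_toy_ontology",
    "make_random_dag",
    "make_class_ontology",
    "make_class_annotations",
    "oracle_paths_up",
    "oracle_paths_down",
    "oracle_contributions",
    "oracle_sv",
    "oracle_depth",
    "oracle_lca_set",
    "oracle_hcd_set",
]

#: symbolic name -> term ID for the toy ontology
TOY = {
    "R": "GO:0000001",
    "C1": "GO:0000002",
    "C2": "GO:0000003",
    "A": "GO:0000004",
    "B": "GO:0000005",
    "D": "GO:0000006",
}
_TOY_NS = "molecular_function"


def make_toy_ontology(include_descendant: bool = False) -> OntologyGraph:
    """The worked-example graph: R <- C1 <- {A, B}, R <- C2, all ``is_a``.

    With ``include_descendant`` a term D is added below both A and B, giving
    the pair a common descendant.
    """
    names = ["R", "C1", "C2", "A", "B"] + (["D"] if include_descendant else [])
    terms = [Term(TOY[n], n, _TOY_NS) for n in names]
    edges = [
        (TOY["C1"], TOY["R"], RelationType.IS_A),
        (TOY["C2"], TOY["R"], RelationType.IS_A),
        (TOY["A"], TOY["C1"], RelationType.IS_A),
        (TOY["B"], TOY["C1"], RelationType.IS_A),
    ]
    if include_descendant:
        edges += [
            (TOY["D"], TOY["A"], RelationType.IS_A),
            (TOY["D"], TOY["B"], RelationType.IS_A),
        ]
    return OntologyGraph(terms, edges, meta={"ontology": "ontosim-toy"})


@dataclass(frozen=True)
class SyntheticOntologySpec:
    """Parameters of a random layered DAG (edges only toward shallower layers)."""

    n_layers: int = 4
    terms_per_layer: int = 5
    edge_density: float = 0.3
    relation_mix: tuple[float, float, float] = (0.7, 0.2, 0.1)  # is_a/part_of/regulates
    seed: int = 0
    namespace: str = "molecular_function"


_REL_CHOICES = (RelationType.IS_A, RelationType.PART_OF, RelationType.REGULATES)


def make_random_dag(spec: SyntheticOntologySpec) -> OntologyGraph:
    """Seeded layered DAG: single root at layer 0, every deeper node gets at
    least one parent in the layer above, plus density-controlled extra edges
    to any strictly shallower layer."""
    rng = np.random.default_rng(spec.seed)
    layers: list[list[str]] = [[f"GO:{1000000}"]]
    terms = [Term(layers[0][0], "root", spec.namespace)]
    edges: list[tuple[str, str, RelationType]] = []
    counter = 1
    for li in range(1, spec.n_layers):
        layer: list[str] = []
        for _ in range(spec.terms_per_layer):
            tid = f"GO:{1000000 + counter}"
            counter += 1
            layer.append(tid)
            terms.append(Term(tid, f"t{counter}", spec.namespace))
            # mandatory parent in the previous layer
            parent = layers[li - 1][rng.integers(len(layers[li - 1]))]
            rel = _REL_CHOICES[rng.choice(3, p=spec.relation_mix)]
            edges.append((tid, parent, rel))
            # optional extra parents anywhere shallower
            for shallow in layers[:li]:
                for cand in shallow:
                    if cand != parent and rng.random() < spec.edge_density / max(
                        1, sum(len(l) for l in layers[:li])
                    ) * spec.terms_per_layer:
                        rel = _REL_CHOICES[rng.choice(3, p=spec.relation_mix)]
                        edges.append((tid, cand, rel))
        layers.append(layer)
    # deduplicate multi-edges between the same pair, keep first
    seen: set[tuple[str, str]] = set()
    uniq = []
    for c, p, r in edges:
        if (c, p) not in seen:
            seen.add((c, p))
            uniq.append((c, p, r))
    return OntologyGraph(terms, uniq, meta={"ontology": "ontosim-random"})


def make_class_ontology(
    n_classes: int = 6,
    depth: int = 3,
    branching: int = 2,
    seed: int = 0,
    namespace: str = "molecular_function",
) -> OntologyGraph:
    """Ontology with ``n_classes`` disjoint subtrees under the root.

    Each class anchor is a child of the root carrying its own ``branching``-ary
    tree of the given depth, so annotation classes anchored at distinct
    branches are perfectly separable.  All edges are ``is_a``.
    """
    terms = [Term("GO:2000000", "root", namespace)]
    edges: list[tuple[str, str, RelationType]] = []
    counter = 1

    def new_term(name: str) -> str:
        nonlocal counter
        tid = f"GO:{2000000 + counter}"
        counter += 1
        terms.append(Term(tid, name, namespace))
        return tid

    for c in range(n_classes):
        anchor = new_term(f"class{c}")
        edges.append((anchor, "GO:2000000", RelationType.IS_A))
        frontier = [anchor]
        for d in range(depth - 1):
            nxt = []
            for parent in frontier:
                for b in range(branching):
                    child = new_term(f"class{c}_d{d + 1}_{b}")
                    edges.append((child, parent, RelationType.IS_A))
                    nxt.append(child)
            frontier = nxt
    return OntologyGraph(terms, edges, meta={"ontology": "ontosim-classes"})


def make_class_annotations(
    g: OntologyGraph,
    n_classes: int = 6,
    genes_per_class: int = 20,
    terms_per_gene: int = 3,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[list[GeneAnnotationSet], dict[str, str]]:
    """Class-structured gene annotation sets with uniform-replacement noise.

    Classes are anchored at the first ``n_classes`` children of the root
    (sorted); each gene samples ``terms_per_gene`` distinct terms from its
    anchor's subtree (anchor included).  Each sampled term is replaced, with
    probability ``noise``, by a uniform draw from all non-root terms — the
    noise model for unreviewed electronic annotations.  Returns the gene
    sets plus a gene -> class-label map.
    """
    rng = np.random.default_rng(seed)
    root = g.roots[sorted(g.roots)[0]]
    anchors = sorted(c for c, _ in g.children[root])[:n_classes]
    if len(anchors) < n_classes:
        raise ValueError(
            f"root has {len(anchors)} children; need {n_classes} class anchors"
        )
    all_terms = sorted(t for t in g.terms if t != root)
    aspect = {"molecular_function": "MF", "biological_process": "BP",
              "cellular_component": "CC"}.get(g.terms[root].namespace, "MF")
    gene_sets: list[GeneAnnotationSet] = []
    labels: dict[str, str] = {}
    for ci, anchor in enumerate(anchors):
        pool = sorted(g.descendants(anchor) | {anchor})
        if len(pool) < terms_per_gene:
            raise ValueError(
                f"class anchor {anchor} subtree has {len(pool)} terms "
                f"< terms_per_gene={terms_per_gene}"
            )
        for gi in range(genes_per_class):
            picked = [pool[i] for i in rng.choice(len(pool), size=terms_per_gene,
                                                  replace=False)]
            final = set()
            for t in picked:
                if rng.random() < noise:
                    t = all_terms[rng.integers(len(all_terms))]
                final.add(t)
            gene = f"gene_c{ci}_{gi:03d}"
            gene_sets.append(GeneAnnotationSet(gene, final, aspect))
            labels[gene] = f"class{ci}"
    return gene_sets, labels


# -- brute-force oracles (tests only; no shared traversal code) ----------------


def oracle_paths_up(g: OntologyGraph, a: str) -> list[list[tuple[str, float]]]:
    """All simple edge-paths from ``a`` to the namespace root, as
    ``(node, edge weight into node)`` lists starting at the anchor."""
    return _enumerate(g, a, g.parents, DEFAULT_WEIGHTS, stop_at_sinks=True)


def _enumerate(g, a, adjacency, w, stop_at_sinks):
    a = g.resolve(a)
    out: list[list[tuple[str, float]]] = []

    def walk(node: str, path: list[tuple[str, float]]) -> None:
        nxt = adjacency[node]
        if not nxt:
            out.append(list(path))
            return
        if not stop_at_sinks:
            out.append(list(path))
        for other, rel in nxt:
            path.append((other, w.weight(rel)))
            walk(other, path)
            path.pop()

    walk(a, [(a, 1.0)])
    return out


def oracle_contributions(
    g: OntologyGraph,
    a: str,
    direction: str = "up",
    w: WeightConfig = DEFAULT_WEIGHTS,
    root_zeroed: bool = True,
    depth_cut: int | None = None,
) -> dict[str, float]:
    """Per-term max path-product contributions by explicit path enumeration."""
    a = g.resolve(a)
    adjacency = g.parents if direction == "up" else g.children
    contrib: dict[str, float] = {}

    def walk(node: str, product: float) -> None:
        if product > contrib.get(node, -1.0):
            contrib[node] = product
        for other, rel in adjacency[node]:
            walk(other, product * w.weight(rel))

    walk(a, 1.0)
    if direction == "up" and root_zeroed:
        root = g.root_of(a)
        if root in contrib:
            contrib[root] = 0.0
    if direction == "down" and depth_cut is not None:
        base = oracle_depth(g, a)
        contrib = {
            t: v
            for t, v in contrib.items()
            if oracle_depth(g, t) - base <= depth_cut
        }
    return contrib


def oracle_sv(
    g: OntologyGraph,
    a: str,
    mode: str = "sum",
    w: WeightConfig = DEFAULT_WEIGHTS,
    root_zeroed: bool = True,
    depth_cut: int | None = None,
) -> float:
    """Semantic value by enumeration: ``sum``, ``max_path`` or ``down_sum``."""
    a = g.resolve(a)
    if mode == "sum":
        return sum(oracle_contributions(g, a, "up", w, root_zeroed).values())
    if mode == "down_sum":
        return sum(
            oracle_contributions(g, a, "down", w, depth_cut=depth_cut).values()
        )
    if mode != "max_path":
        raise ValueError(f"unknown mode {mode!r}")
    root = g.root_of(a)
    best = None
    for path in oracle_paths_up(g, a):
        total, product = 0.0, 1.0
        for node, we in path:
            product *= we
            contribution = product  # anchor's entry has we == 1
            if root_zeroed and node == root:
                contribution = 0.0
            total += contribution
        if path[-1][0] == root and (best is None or total > best):
            best = total
    if best is None:  # anchor is the root itself
        best = 0.0 if root_zeroed else 1.0
    return best


def oracle_depth(g: OntologyGraph, a: str, longest: bool = True) -> int:
    """Depth by enumerating every path from the term up to the root."""
    lengths = [len(p) - 1 for p in oracle_paths_up(g, a)]
    return max(lengths) if longest else min(lengths)


def oracle_lca_set(g: OntologyGraph, a: str, b: str) -> set[str]:
    """All deepest common ancestors (terms count as their own ancestors)."""
    anc_a = {node for p in oracle_paths_up(g, a) for node, _ in p}
    anc_b = {node for p in oracle_paths_up(g, b) for node, _ in p}
    common = anc_a & anc_b
    if not common:
        return set()
    dmax = max(oracle_depth(g, t) for t in common)
    return {t for t in common if oracle_depth(g, t) == dmax}


def oracle_hcd_set(g: OntologyGraph, a: str, b: str) -> set[str]:
    """All shallowest strict common descendants."""
    a, b = g.resolve(a), g.resolve(b)
    desc_a = set(oracle_contributions(g, a, "down")) - {a}
    desc_b = set(oracle_contributions(g, b, "down")) - {b}
    common = desc_a & desc_b
    if not common:
        return set()
    dmin = min(oracle_depth(g, t) for t in common)
    return {t for t in common if oracle_depth(g, t) == dmin}
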