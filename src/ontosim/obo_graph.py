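"""Typed ontology DAG: parsing, traversal, depths, LCA and HCD queries.

The Gene Ontology is three rooted DAGs (molecular_function, biological_process,
cellular_component) whose terms are linked by typed relationships.  This module
loads a go-basic style OBO file into an :class:`OntologyGraph` restricted to
the relationship types that carry semantic weight here — ``is_a``, ``part_of``
and the ``regulates`` family — and provides the graph queries every similarity
measure is built on: ancestor/descendant closures, longest- and shortest-path
depths, the lowest common ancestor (LCA) and the highest common descendant
(HCD).

Conventions
-----------
* Edges point child -> parent ("toward the root").
* Cross-namespace relationships are dropped: similarity is defined per aspect.
* Obsolete terms are parsed but excluded from traversal; ``alt_id`` entries
  resolve to their canonical term.
* ``lca`` treats each query term as its own ancestor; ``hcd`` uses *strict*
  descendants, so two leaves have no common descendant.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import networkx as nx
import obonet

from .errors import IntegrityError, NoCommonAncestorError, ParseError, UnknownTermError

__all__ = [
    "RelationType",
    "Term",
    "OntologyGraph",
    "parse_obo",
    "write_obo",
    "ancestors",
    "descendants",
    "depth_longest",
    "depth_shortest",
    "lca",
    "hcd",
    "ASPECT_NAMESPACES",
    "NAMESPACE_ASPECTS",
]

#: GO aspect code -> OBO namespace string.
ASPECT_NAMESPACES = {
    "MF": "molecular_function",
    "BP": "biological_process",
    "CC": "cellular_component",
}
NAMESPACE_ASPECTS = {v: k for k, v in ASPECT_NAMESPACES.items()}


class RelationType(enum.Enum):
    """Typed parent relationships traversed by the similarity measures."""

    IS_A = "is_a"
    PART_OF = "part_of"
    REGULATES = "regulates"
    POSITIVELY_REGULATES = "positively_regulates"
    NEGATIVELY_REGULATES = "negatively_regulates"

    @classmethod
    def from_tag(cls, tag: str) -> "RelationType | None":
        try:
            return cls(tag)
        except ValueError:
            return None  # occurs_in, has_part, ... are ignored


@dataclass(frozen=True)
class Term:
    id: str
    name: str = ""
    namespace: str = ""


class OntologyGraph:
    """A validated, namespaced DAG of ontology terms with typed parent edges.

    Parameters
    ----------
    terms
        The non-obsolete terms of the ontology.
    edges
        ``(child, parent, relation)`` triples; edges whose endpoints live in
        different namespaces (or touch obsolete/unknown terms) are dropped.
    alt_ids
        Mapping of alternate ID -> canonical ID.
    obsolete
        IDs of obsolete terms (kept for error reporting, never traversed).
    meta
        Free-form header metadata (e.g. ``data-version`` from the OBO file).
    """

    def __init__(
        self,
        terms: Iterable[Term],
        edges: Iterable[tuple[str, str, RelationType]],
        alt_ids: Mapping[str, str] | None = None,
        obsolete: Iterable[str] | None = None,
        meta: Mapping[str, str] | None = None,
        validate: bool = True,
    ) -> None:
        self.terms: dict[str, Term] = {t.id: t for t in terms}
        self.obsolete: frozenset[str] = frozenset(obsolete or ())
        self.alt_ids: dict[str, str] = dict(alt_ids or {})
        self.meta: dict[str, str] = dict(meta or {})
        self.parents: dict[str, list[tuple[str, RelationType]]] = {
            t: [] for t in self.terms
        }
        self.children: dict[str, list[tuple[str, RelationType]]] = {
            t: [] for t in self.terms
        }
        for child, parent, rel in edges:
            if child in self.obsolete or parent in self.obsolete:
                continue
            if child not in self.terms or parent not in self.terms:
                continue
            if self.terms[child].namespace != self.terms[parent].namespace:
                continue
            self.parents[child].append((parent, rel))
            self.children[parent].append((child, rel))
        # deterministic adjacency order
        for adj in (self.parents, self.children):
            for k in adj:
                adj[k].sort(key=lambda e: (e[0], e[1].value))
        self.roots: dict[str, str] = self._find_roots()
        self._depth_long: dict[str, int] = {}
        self._depth_short: dict[str, int] = {}
        if validate:
            self._validate()

    # -- construction helpers -------------------------------------------------

    def _find_roots(self) -> dict[str, str]:
        roots: dict[str, str] = {}
        for tid, term in sorted(self.terms.items()):
            if not self.parents[tid]:
                if term.namespace in roots:
                    raise IntegrityError(
                        f"namespace {term.namespace!r} has multiple parentless "
                        f"terms: {roots[term.namespace]}, {tid}"
                    )
                roots[term.namespace] = tid
        return roots

    def _validate(self) -> None:
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.terms)
        for child, plist in self.parents.items():
            for parent, rel in plist:
                g.add_edge(child, parent, key=rel.value)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise IntegrityError(f"cyclic namespace subgraph: {cycle}")

    # -- lookups --------------------------------------------------------------

    def resolve(self, term_id: str) -> str:
        """Canonical ID for ``term_id``, resolving ``alt_id`` entries first."""
        if term_id in self.alt_ids:
            term_id = self.alt_ids[term_id]
        if term_id in self.obsolete:
            raise UnknownTermError(f"term {term_id} is obsolete")
        if term_id not in self.terms:
            raise UnknownTermError(f"unknown term {term_id}")
        return term_id

    def namespace_of(self, term_id: str) -> str:
        return self.terms[self.resolve(term_id)].namespace

    def root_of(self, term_id: str) -> str:
        """Root of the namespace the term belongs to."""
        return self.roots[self.namespace_of(term_id)]

    def __contains__(self, term_id: str) -> bool:
        try:
            self.resolve(term_id)
        except UnknownTermError:
            return False
        return True

    def __len__(self) -> int:
        return len(self.terms)

    # -- traversal ------------------------------------------------------------

    def ancestors(self, term_id: str) -> set[str]:
        """Transitive parents of the term (excluding the term itself)."""
        a = self.resolve(term_id)
        seen: set[str] = set()
        stack = [p for p, _ in self.parents[a]]
        while stack:
            t = stack.pop()
            if t not in seen:
                seen.add(t)
                stack.extend(p for p, _ in self.parents[t])
        return seen

    def descendants(self, term_id: str) -> set[str]:
        """Transitive children of the term (excluding the term itself)."""
        a = self.resolve(term_id)
        seen: set[str] = set()
        stack = [c for c, _ in self.children[a]]
        while stack:
            t = stack.pop()
            if t not in seen:
                seen.add(t)
                stack.extend(c for c, _ in self.children[t])
        return seen

    def depth_longest(self, term_id: str) -> int:
        """Edge count of the longest root-to-term path (root -> 0)."""
        a = self.resolve(term_id)
        return self._depth(a, self._depth_long, max)

    def depth_shortest(self, term_id: str) -> int:
        """Edge count of the shortest root-to-term path (root -> 0)."""
        a = self.resolve(term_id)
        return self._depth(a, self._depth_short, min)

    def _depth(
        self, a: str, cache: dict[str, int], agg: Callable[[Iterable[int]], int]
    ) -> int:
        # iterative post-order so deep ontologies don't hit recursion limits
        stack = [a]
        while stack:
            t = stack[-1]
            if t in cache:
                stack.pop()
                continue
            ps = [p for p, _ in self.parents[t]]
            pending = [p for p in ps if p not in cache]
            if pending:
                stack.extend(pending)
                continue
            cache[t] = agg(cache[p] for p in ps) + 1 if ps else 0
            stack.pop()
        return cache[a]

    # -- LCA / HCD ------------------------------------------------------------

    def lca(
        self, a: str, b: str, sv_fn: Callable[[str], float] | None = None
    ) -> str:
        """Lowest common ancestor of ``a`` and ``b``.

        Each term counts as its own ancestor.  Among common ancestors the one
        with maximal longest-path depth wins; ties are broken by maximal
        ``sv_fn`` (semantic value) when given, then by lexicographically
        smallest term ID.
        """
        a, b = self.resolve(a), self.resolve(b)
        common = (self.ancestors(a) | {a}) & (self.ancestors(b) | {b})
        if not common:
            raise NoCommonAncestorError(
                f"{a} and {b} share no ancestor (different namespaces?)"
            )
        max_depth = max(self.depth_longest(t) for t in common)
        deepest = sorted(t for t in common if self.depth_longest(t) == max_depth)
        if len(deepest) > 1 and sv_fn is not None:
            max_sv = max(sv_fn(t) for t in deepest)
            deepest = [t for t in deepest if sv_fn(t) == max_sv]
        return deepest[0]

    def hcd(self, a: str, b: str) -> str | None:
        """Highest (shallowest) strict common descendant, or ``None``.

        Ties at the minimal longest-path depth are broken lexicographically.
        """
        a, b = self.resolve(a), self.resolve(b)
        common = self.descendants(a) & self.descendants(b)
        if not common:
            return None
        min_depth = min(self.depth_longest(t) for t in common)
        return min(t for t in common if self.depth_longest(t) == min_depth)

    def edge_multiset(self) -> list[tuple[str, str, str]]:
        """Sorted ``(child, parent, relation)`` triples — round-trip checks."""
        return sorted(
            (c, p, rel.value)
            for c, plist in self.parents.items()
            for p, rel in plist
        )


# -- module-level functional surface ------------------------------------------


def ancestors(g: OntologyGraph, a: str) -> set[str]:
    return g.ancestors(a)


def descendants(g: OntologyGraph, a: str) -> set[str]:
    return g.descendants(a)


def depth_longest(g: OntologyGraph, a: str) -> int:
    return g.depth_longest(a)


def depth_shortest(g: OntologyGraph, a: str) -> int:
    return g.depth_shortest(a)


def lca(g: OntologyGraph, a: str, b: str, sv_fn=None) -> str:
    return g.lca(a, b, sv_fn=sv_fn)


def hcd(g: OntologyGraph, a: str, b: str) -> str | None:
    return g.hcd(a, b)


# -- OBO I/O -------------------------------------------------------------------


def parse_obo(path) -> OntologyGraph:
    """Read an OBO 1.2/1.4 flat file (go-basic dialect) into an OntologyGraph.

    ``is_a`` lines and ``relationship:`` lines of the part_of/regulates family
    become typed parent edges; other relationship types are ignored; edges
    crossing namespaces are dropped; obsolete terms are flagged and excluded
    from traversal.
    """
    try:
        raw = obonet.read_obo(path, ignore_obsolete=False)
    except Exception as exc:  # obonet raises ValueError naming the stanza line
        raise ParseError(f"cannot parse OBO file {path!r}: {exc}") from exc

    terms: list[Term] = []
    obsolete: set[str] = set()
    alt_ids: dict[str, str] = {}
    for tid, data in raw.nodes(data=True):
        if data.get("is_obsolete") == "true":
            obsolete.add(tid)
            continue
        terms.append(Term(tid, data.get("name", ""), data.get("namespace", "")))
        for alt in data.get("alt_id", []):
            alt_ids[alt] = tid

    edges: list[tuple[str, str, RelationType]] = []
    # obonet edges run child -> parent with the relationship tag as the key
    for child, parent, tag in raw.edges(keys=True):
        rel = RelationType.from_tag(tag)
        if rel is not None:
            edges.append((child, parent, rel))

    meta = {
        k: v
        for k, v in raw.graph.items()
        if isinstance(v, str) and k in ("format-version", "data-version", "ontology")
    }
    return OntologyGraph(terms, edges, alt_ids=alt_ids, obsolete=obsolete, meta=meta)


def write_obo(g: OntologyGraph, path) -> None:
    """Serialize a graph back to a minimal OBO 1.2 flat file.

    Only the tags this package reads are emitted (id, name, namespace, alt_id,
    is_a, relationship, is_obsolete), which is enough for round-tripping
    fixtures and for down-sampled ontology excerpts.
    """
    canon_to_alts: dict[str, list[str]] = {}
    for alt, canon in sorted(g.alt_ids.items()):
        canon_to_alts.setdefault(canon, []).append(alt)
    with open(path, "w") as fh:
        fh.write(f"format-version: {g.meta.get('format-version', '1.2')}\n")
        if "data-version" in g.meta:
            fh.write(f"data-version: {g.meta['data-version']}\n")
        fh.write(f"ontology: {g.meta.get('ontology', 'ontosim-fixture')}\n")
        for tid in sorted(g.terms):
            term = g.terms[tid]
            fh.write(f"\n[Term]\nid: {tid}\n")
            if term.name:
                fh.write(f"name: {term.name}\n")
            if term.namespace:
                fh.write(f"namespace: {term.namespace}\n")
            for alt in canon_to_alts.get(tid, []):
                fh.write(f"alt_id: {alt}\n")
            for parent, rel in g.parents[tid]:
                if rel is RelationType.IS_A:
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel.value} {parent}\n")
        for tid in sorted(g.obsolete):
            fh.write(f"\n[Term]\nid: {tid}\nis_obsolete: true\n")
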