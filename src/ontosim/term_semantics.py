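"""Semantic contributions, semantic values and term-pair similarity measures.

The family of measures implemented here scores a pair of ontology terms by how
much of the weighted graph structure they share:

* **Contributions** (upward or downward): every ancestor (or descendant) ``t``
  of an anchor term ``A`` receives ``S_A(t)``, the maximum over connecting
  paths of the product of edge weights along the path.  Edge weights encode
  relationship strength (defaults ``is_a`` 0.8, ``part_of`` 0.6, ``regulates``
  0.7).  In root-zeroed mode the namespace root contributes 0 — the direct
  children of a root are not similar, so the root should not inflate scores.
* **Semantic values** aggregate a contribution map: the *sum* over all terms,
  or the *max-path* value — the best single root-reaching path, where each
  node on a path contributes the edge-weight product accumulated along that
  particular path.
* **Similarities**: ratio-of-shared-contributions measures (baseline / Wang /
  Tanimoto), an LCA-anchored upward measure, a common-descendant downward
  measure, and their mixtures; plus the classical information-content
  (Resnik, Lin) and depth (Wu–Palmer) baselines for comparison.

All bounded measures are symmetric, lie in [0, 1] and score identical terms
as 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal

import pandas as pd

from .errors import DataError
from .obo_graph import OntologyGraph, RelationType

__all__ = [
    "WeightConfig",
    "ContributionMap",
    "SemanticValue",
    "TermPairResult",
    "ICTable",
    "contributions_up",
    "contributions_down",
    "sv_sum",
    "sv_max_path",
    "sim_baseline",
    "sim_wang",
    "sim_lca",
    "sim_desc",
    "sim_gontosim",
    "sim_baseline_desc",
    "sim_baseline_lca",
    "sim_tanimoto",
    "build_ic",
    "sim_resnik",
    "sim_lin",
    "wu_palmer",
    "MEASURES",
    "term_similarity",
    "pairwise_table",
]


@dataclass(frozen=True)
class WeightConfig:
    """Edge weights per relationship class and the upward/downward mix.

    ``positively_regulates`` / ``negatively_regulates`` share the plain
    ``regulates`` weight.  ``U`` and ``L`` mix the upward (ancestor-based) and
    downward (descendant-based) similarity components and must sum to 1.
    """

    w_is_a: float = 0.8
    w_part_of: float = 0.6
    w_regulates: float = 0.7
    U: float = 0.5
    L: float = 0.5

    def __post_init__(self) -> None:
        for name in ("w_is_a", "w_part_of", "w_regulates"):
            w = getattr(self, name)
            if not 0 < w <= 1:
                raise ValueError(f"{name}={w} outside (0, 1]")
        if not math.isclose(self.U + self.L, 1.0, abs_tol=1e-9):
            raise ValueError(f"U + L must equal 1, got {self.U} + {self.L}")

    def weight(self, rel: RelationType) -> float:
        if rel is RelationType.IS_A:
            return self.w_is_a
        if rel is RelationType.PART_OF:
            return self.w_part_of
        return self.w_regulates  # regulates family, +/- folded in


DEFAULT_WEIGHTS = WeightConfig()


@dataclass
class ContributionMap:
    """Per-term contributions ``S_A(t)`` of the anchor's upward/downward DAG."""

    anchor: str
    direction: Literal["up", "down"]
    contributions: dict[str, float]
    root_zeroed: bool = False
    depth_cut: int | None = None

    def __getitem__(self, term: str) -> float:
        return self.contributions[term]

    def terms(self) -> set[str]:
        return set(self.contributions)


@dataclass(frozen=True)
class SemanticValue:
    term: str
    mode: Literal["sum", "max_path", "down_sum"]
    value: float


@dataclass(frozen=True)
class TermPairResult:
    a: str
    b: str
    measure: str
    upward: float
    downward: float
    total: float
    lca_used: str | None = None
    hcd_used: str | None = None


# -- contributions and semantic values ----------------------------------------


def contributions_up(
    g: OntologyGraph,
    a: str,
    w: WeightConfig = DEFAULT_WEIGHTS,
    root_zeroed: bool = True,
) -> ContributionMap:
    """Contribution of every term in the anchor's upward DAG.

    ``S_A(A) = 1``; an ancestor ``t`` gets the maximum over a -> t paths of
    the product of edge weights, computed by dynamic programming over the
    DAG (each ancestor takes the best weighted hand-off from the members of
    the upward DAG below it).  With ``root_zeroed`` the namespace root is
    forced to 0.
    """
    a = g.resolve(a)
    dag = g.ancestors(a) | {a}
    # process deepest-first: a parent is never deeper than its child
    order = sorted(dag, key=lambda t: (-g.depth_longest(t), t))
    contrib: dict[str, float] = {}
    for t in order:
        if t == a:
            contrib[t] = 1.0
            continue
        contrib[t] = max(
            w.weight(rel) * contrib[c]
            for c, rel in g.children[t]
            if c in contrib
        )
    root = g.root_of(a)
    if root_zeroed and root in contrib:
        contrib[root] = 0.0
    return ContributionMap(a, "up", contrib, root_zeroed=root_zeroed)


def contributions_down(
    g: OntologyGraph,
    a: str,
    w: WeightConfig = DEFAULT_WEIGHTS,
    depth_cut: int | None = None,
) -> ContributionMap:
    """Mirror of :func:`contributions_up` over descendant edges.

    Only descendants within ``depth_cut`` levels below the anchor are kept,
    levels measured as the difference in longest-path depth from the root.
    No root-zeroing applies downward.
    """
    a = g.resolve(a)
    d_a = g.depth_longest(a)
    dag = {
        t
        for t in g.descendants(a)
        if depth_cut is None or g.depth_longest(t) - d_a <= depth_cut
    }
    dag.add(a)
    order = sorted(dag, key=lambda t: (g.depth_longest(t), t))
    contrib: dict[str, float] = {}
    for t in order:
        if t == a:
            contrib[t] = 1.0
            continue
        contrib[t] = max(
            w.weight(rel) * contrib[p]
            for p, rel in g.parents[t]
            if p in contrib
        )
    return ContributionMap(a, "down", contrib, depth_cut=depth_cut)


def sv_sum(cmap: ContributionMap) -> SemanticValue:
    """Total semantic value: sum of all contributions in the map."""
    mode = "sum" if cmap.direction == "up" else "down_sum"
    return SemanticValue(cmap.anchor, mode, sum(cmap.contributions.values()))


def sv_max_path(
    g: OntologyGraph,
    a: str,
    w: WeightConfig = DEFAULT_WEIGHTS,
    root_zeroed: bool = True,
) -> SemanticValue:
    """Semantic value of the single best root-reaching path.

    Each node on a path contributes the product of edge weights accumulated
    along that path (anchor 1, root 0 when zeroed); the value is the maximum
    path sum.  Computed with a Pareto-front sweep over (path sum, path
    product) states, so no explicit path enumeration is needed.
    """
    a = g.resolve(a)
    root = g.root_of(a)
    if a == root:
        return SemanticValue(a, "max_path", 0.0 if root_zeroed else 1.0)
    dag = g.ancestors(a) | {a}
    order = sorted(dag, key=lambda t: (-g.depth_longest(t), t))
    # states[t]: Pareto-maximal (sum, product) pairs over a -> t paths
    states: dict[str, list[tuple[float, float]]] = {a: [(1.0, 1.0)]}
    for t in order:
        for p, rel in g.parents[t]:
            if p not in dag or t not in states:
                continue
            we = w.weight(rel)
            new = []
            for s, prod in states[t]:
                c = prod * we
                contrib = 0.0 if (root_zeroed and p == root) else c
                new.append((s + contrib, c))
            states[p] = _pareto(states.get(p, []) + new)
    if root not in states:  # pragma: no cover - guaranteed by validation
        raise DataError(f"no path from {a} to namespace root {root}")
    return SemanticValue(a, "max_path", max(s for s, _ in states[root]))


def _pareto(pairs: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Keep states not dominated in both path-sum and path-product."""
    pairs = sorted(set(pairs), key=lambda x: (-x[0], -x[1]))
    front: list[tuple[float, float]] = []
    best_prod = -1.0
    for s, p in pairs:
        if p > best_prod:
            front.append((s, p))
            best_prod = p
    return front


# -- ratio-of-contributions measures ------------------------------------------


def sim_baseline(
    g: OntologyGraph,
    a: str,
    b: str,
    w: WeightConfig = DEFAULT_WEIGHTS,
    root_zeroed: bool = True,
    measure_name: str = "baseline",
) -> TermPairResult:
    """Shared upward contributions over total semantic values.

    ``sum_(t in T_A ∩ T_B) (S_A(t) + S_B(t)) / (SV(A) + SV(B))`` with sum-mode
    semantic values.  With ``root_zeroed=False`` this is exactly Wang's
    structural-IC measure.
    """
    a, b = g.resolve(a), g.resolve(b)
    if a == b:  # intersection is the full set: exact identity
        return TermPairResult(a, b, measure_name, 1.0, 0.0, 1.0)
    ca = contributions_up(g, a, w, root_zeroed=root_zeroed)
    cb = contributions_up(g, b, w, root_zeroed=root_zeroed)
    shared = ca.terms() & cb.terms()
    num = sum(ca[t] + cb[t] for t in shared)
    den = sv_sum(ca).value + sv_sum(cb).value
    total = _ratio(num, den, identity=False)
    return TermPairResult(a, b, measure_name, upward=total, downward=0.0, total=total)


def sim_wang(
    g: OntologyGraph, a: str, b: str, w: WeightConfig = DEFAULT_WEIGHTS
) -> TermPairResult:
    """Wang's measure: the baseline ratio with the root contributing normally."""
    r = sim_baseline(g, a, b, w, root_zeroed=False, measure_name="wang")
    return r


def sim_tanimoto(
    g: OntologyGraph,
    a: str,
    b: str,
    w: WeightConfig = DEFAULT_WEIGHTS,
    base: Literal["baseline", "gontosim"] = "baseline",
) -> TermPairResult:
    """Weighted-set Tanimoto over contribution maps.

    ``sum_t min(S_A(t), S_B(t)) / sum_t max(S_A(t), S_B(t))`` with missing
    terms contributing 0.  The ``baseline`` variant scores the upward
    (root-zeroed) maps; the ``gontosim`` variant mixes the upward Tanimoto
    with a Tanimoto over the HCD-truncated downward maps using U/L.
    """
    a, b = g.resolve(a), g.resolve(b)
    up = _tanimoto(
        contributions_up(g, a, w).contributions,
        contributions_up(g, b, w).contributions,
        identity=a == b,
    )
    if base == "baseline":
        return TermPairResult(a, b, "tanimoto_baseline", up, 0.0, up)
    if base != "gontosim":
        raise ValueError(f"unknown tanimoto base {base!r}")
    h = g.hcd(a, b)
    if h is None:
        down = 0.0
    else:
        dh = g.depth_longest(h)
        da = contributions_down(g, a, w, depth_cut=dh - g.depth_longest(a))
        db = contributions_down(g, b, w, depth_cut=dh - g.depth_longest(b))
        down = _tanimoto(da.contributions, db.contributions, identity=a == b)
    total = 1.0 if a == b else w.U * up + w.L * down
    return TermPairResult(a, b, "tanimoto_gontosim", up, down, total, hcd_used=h)


def _tanimoto(sa: dict[str, float], sb: dict[str, float], identity: bool) -> float:
    union = set(sa) | set(sb)
    num = sum(min(sa.get(t, 0.0), sb.get(t, 0.0)) for t in union)
    den = sum(max(sa.get(t, 0.0), sb.get(t, 0.0)) for t in union)
    return _ratio(num, den, identity=identity)


# -- LCA / descendant measures -------------------------------------------------


def sim_lca(
    g: OntologyGraph,
    a: str,
    b: str,
    w: WeightConfig = DEFAULT_WEIGHTS,
    measure_name: str = "baseline_lca",
) -> TermPairResult:
    """Upward similarity anchored at the LCA.

    ``2 * SV(LCA) / (SV(A) + SV(B))`` with max-path semantic values; the LCA
    tie-break uses the same max-path SV.
    """
    a, b = g.resolve(a), g.resolve(b)
    sv = lambda t: sv_max_path(g, t, w).value  # noqa: E731
    l = g.lca(a, b, sv_fn=sv)
    num = 2.0 * sv(l)
    den = sv(a) + sv(b)
    total = _ratio(num, den, identity=a == b)
    return TermPairResult(a, b, measure_name, total, 0.0, total, lca_used=l)


def sim_baseline_lca(
    g: OntologyGraph, a: str, b: str, w: WeightConfig = DEFAULT_WEIGHTS
) -> TermPairResult:
    """Ablation: the LCA-anchored upward similarity reported on its own."""
    return sim_lca(g, a, b, w, measure_name="baseline_lca")


def sim_desc(
    g: OntologyGraph, a: str, b: str, w: WeightConfig = DEFAULT_WEIGHTS
) -> TermPairResult:
    """Downward similarity via common descendants.

    The highest common descendant (HCD) sets a per-term truncation depth
    ``depth(HCD) - depth(X)``; shared truncated downward contributions are
    divided by the two truncated downward semantic values (anchors included).
    No common descendant means zero downward similarity.
    """
    a, b = g.resolve(a), g.resolve(b)
    h = g.hcd(a, b)
    if h is None:
        return TermPairResult(a, b, "desc", 0.0, 0.0, 0.0, hcd_used=None)
    if a == b:  # all downward sets coincide
        return TermPairResult(a, b, "desc", 0.0, 1.0, 1.0, hcd_used=h)
    dh = g.depth_longest(h)
    ca = contributions_down(g, a, w, depth_cut=dh - g.depth_longest(a))
    cb = contributions_down(g, b, w, depth_cut=dh - g.depth_longest(b))
    shared = ca.terms() & cb.terms()
    num = sum(ca[t] + cb[t] for t in shared)
    den = sv_sum(ca).value + sv_sum(cb).value
    total = _ratio(num, den, identity=False)
    return TermPairResult(a, b, "desc", 0.0, total, total, hcd_used=h)


def sim_gontosim(
    g: OntologyGraph,
    a: str,
    b: str,
    w: WeightConfig = DEFAULT_WEIGHTS,
    literal_mixture: bool = False,
) -> TermPairResult:
    """Combined measure: ``U * Sim_LCA + L * Sim_Desc`` (default U = L = 0.5).

    Identical terms score exactly 1 by convention — the literal mixture would
    give 0.5 for identical *leaf* terms (no common descendant) which violates
    the identity axiom; pass ``literal_mixture=True`` for the literal behavior.
    """
    up = sim_lca(g, a, b, w)
    down = sim_desc(g, a, b, w)
    total = w.U * up.total + w.L * down.total
    if not literal_mixture and up.a == up.b:
        total = 1.0
    return TermPairResult(
        up.a, up.b, "gontosim", up.total, down.total, total,
        lca_used=up.lca_used, hcd_used=down.hcd_used,
    )


def sim_baseline_desc(
    g: OntologyGraph, a: str, b: str, w: WeightConfig = DEFAULT_WEIGHTS
) -> TermPairResult:
    """Mixture ``U * Sim_Baseline + L * Sim_Desc`` (identity scores 1)."""
    up = sim_baseline(g, a, b, w)
    down = sim_desc(g, a, b, w)
    total = 1.0 if up.a == up.b else w.U * up.total + w.L * down.total
    return TermPairResult(
        up.a, up.b, "baseline_desc", up.total, down.total, total,
        hcd_used=down.hcd_used,
    )


def _ratio(num: float, den: float, identity: bool) -> float:
    if den == 0.0:
        return 1.0 if identity else 0.0
    return num / den


# -- information-content measures ----------------------------------------------


@dataclass
class ICTable:
    """Per-term information content from annotation frequency.

    Each annotation counts toward the annotated term and its full ancestor
    closure (true-path rule); ``P(T) = count(T) / count(namespace root)`` and
    ``IC(T) = -ln P(T)``.  Terms never reached by any annotation have
    infinite IC and are skipped when searching for the most informative
    common ancestor.
    """

    counts: dict[str, int]
    root_counts: dict[str, int]  # namespace -> corpus size
    _ns: dict[str, str] = field(default_factory=dict)  # term -> namespace

    def ic(self, term: str) -> float:
        n = self.counts.get(term, 0)
        total = self.root_counts.get(self._ns.get(term, ""), 0)
        if n == 0 or total == 0:
            return math.inf
        return -math.log(n / total)


def build_ic(annotation_sets: Iterable, g: OntologyGraph) -> ICTable:
    """Estimate term probabilities from a corpus of gene annotation sets.

    ``annotation_sets`` is any iterable of objects with a ``terms`` attribute
    (e.g. :class:`ontosim.annotation_io.GeneAnnotationSet`).
    """
    counts: dict[str, int] = {}
    ns: dict[str, str] = {}
    n_annotations = 0
    for gs in annotation_sets:
        for t in gs.terms:
            t = g.resolve(t)
            n_annotations += 1
            for u in g.ancestors(t) | {t}:
                counts[u] = counts.get(u, 0) + 1
                ns[u] = g.terms[u].namespace
    if n_annotations == 0:
        raise DataError("empty annotation corpus: cannot estimate IC")
    root_counts = {
        nsname: counts.get(root, 0) for nsname, root in g.roots.items()
    }
    return ICTable(counts, root_counts, ns)


def _mica(ic: ICTable, g: OntologyGraph, a: str, b: str) -> tuple[str, float]:
    common = (g.ancestors(a) | {a}) & (g.ancestors(b) | {b})
    best, best_ic = None, -math.inf
    for t in sorted(common):
        v = ic.ic(t)
        if math.isfinite(v) and v > best_ic:
            best, best_ic = t, v
    if best is None:
        root = g.root_of(a)
        return root, 0.0
    return best, best_ic


def sim_resnik(ic: ICTable, g: OntologyGraph, a: str, b: str) -> float:
    """IC of the most informative common ancestor (raw, unbounded above)."""
    a, b = g.resolve(a), g.resolve(b)
    _, v = _mica(ic, g, a, b)
    return v


def sim_lin(ic: ICTable, g: OntologyGraph, a: str, b: str) -> float:
    """``2 IC(MICA) / (IC(a) + IC(b))``; 0 when the denominator vanishes."""
    a, b = g.resolve(a), g.resolve(b)
    _, mica_ic = _mica(ic, g, a, b)
    ia, ib = ic.ic(a), ic.ic(b)
    if not (math.isfinite(ia) and math.isfinite(ib)) or ia + ib == 0.0:
        return 0.0
    return 2.0 * mica_ic / (ia + ib)


def _up_distances(g: OntologyGraph, a: str) -> dict[str, int]:
    """Shortest edge-distance from ``a`` to each of its ancestors (and itself)."""
    dist = {a: 0}
    frontier = [a]
    while frontier:
        nxt = []
        for t in frontier:
            for p, _ in g.parents[t]:
                if p not in dist:
                    dist[p] = dist[t] + 1
                    nxt.append(p)
        frontier = nxt
    return dist


def wu_palmer(g: OntologyGraph, a: str, b: str) -> float:
    """Edge-counting similarity through the lowest common ancestor.

    ``2 N3 / (N1 + N2 + 2 N3)`` where N3 is the shortest-path depth of the
    common ancestor and N1, N2 the shortest distances from each term to it;
    the common ancestor maximizing the score is used.  On a tree this equals
    ``2 depth(LCA) / (depth(a) + depth(b))``; the path-based form keeps the
    score within [0, 1] on DAGs, where a shortcut edge can make a term's
    shortest-path depth smaller than an ancestor's.
    """
    a, b = g.resolve(a), g.resolve(b)
    da, db = _up_distances(g, a), _up_distances(g, b)
    common = set(da) & set(db)
    if not common:
        raise DataError(f"{a} and {b} share no ancestor")
    if a == b:
        return 1.0
    best = 0.0
    for t in sorted(common):
        d3 = g.depth_shortest(t)
        den = da[t] + db[t] + 2.0 * d3
        if den > 0.0:
            best = max(best, 2.0 * d3 / den)
    return best


# -- registry / batch API ------------------------------------------------------


def _wrap_float(fn):
    def run(g, a, b, w=DEFAULT_WEIGHTS, ic=None, name=""):
        if ic is None:
            raise DataError(f"measure {name!r} needs an ICTable (ic=...)")
        v = fn(ic, g, a, b)
        return TermPairResult(g.resolve(a), g.resolve(b), name, v, 0.0, v)

    return run


#: measure name -> callable(g, a, b, w, ic) -> TermPairResult
MEASURES = {
    "gontosim": lambda g, a, b, w, ic=None: sim_gontosim(g, a, b, w),
    "baseline": lambda g, a, b, w, ic=None: sim_baseline(g, a, b, w),
    "baseline_desc": lambda g, a, b, w, ic=None: sim_baseline_desc(g, a, b, w),
    "baseline_lca": lambda g, a, b, w, ic=None: sim_baseline_lca(g, a, b, w),
    "wang": lambda g, a, b, w, ic=None: sim_wang(g, a, b, w),
    "tanimoto_baseline": lambda g, a, b, w, ic=None: sim_tanimoto(g, a, b, w, "baseline"),
    "tanimoto_gontosim": lambda g, a, b, w, ic=None: sim_tanimoto(g, a, b, w, "gontosim"),
    "resnik": lambda g, a, b, w, ic=None: _wrap_float(sim_resnik)(g, a, b, w, ic, "resnik"),
    "lin": lambda g, a, b, w, ic=None: _wrap_float(sim_lin)(g, a, b, w, ic, "lin"),
    "wu_palmer": lambda g, a, b, w, ic=None: _wu_palmer_result(g, a, b),
}


def _wu_palmer_result(g: OntologyGraph, a: str, b: str) -> TermPairResult:
    v = wu_palmer(g, a, b)
    return TermPairResult(g.resolve(a), g.resolve(b), "wu_palmer", v, 0.0, v)

#: measures guaranteed to be symmetric, bounded in [0,1] with identity = 1
BOUNDED_MEASURES = (
    "gontosim",
    "baseline",
    "baseline_desc",
    "baseline_lca",
    "wang",
    "tanimoto_baseline",
    "tanimoto_gontosim",
    "wu_palmer",
)


def term_similarity(
    g: OntologyGraph,
    a: str,
    b: str,
    measure: str = "gontosim",
    w: WeightConfig = DEFAULT_WEIGHTS,
    ic: ICTable | None = None,
) -> TermPairResult:
    """Run a registered measure by name on one term pair."""
    try:
        fn = MEASURES[measure]
    except KeyError:
        raise DataError(
            f"unknown measure {measure!r}; known: {', '.join(sorted(MEASURES))}"
        ) from None
    return fn(g, a, b, w, ic)


def pairwise_table(
    g: OntologyGraph,
    pairs: Iterable[tuple[str, str]],
    measure: str = "gontosim",
    w: WeightConfig = DEFAULT_WEIGHTS,
    ic: ICTable | None = None,
) -> pd.DataFrame:
    """Batch API: term pairs -> DataFrame (term_a, term_b, upward, downward, total)."""
    rows = []
    for a, b in pairs:
        r = term_similarity(g, a, b, measure, w, ic)
        rows.append(
            {"term_a": r.a, "term_b": r.b, "upward": r.upward,
             "downward": r.downward, "total": r.total}
        )
    return pd.DataFrame(rows, columns=["term_a", "term_b", "upward", "downward", "total"])
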