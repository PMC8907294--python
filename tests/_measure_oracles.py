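"""Similarity measures recomputed from exhaustive-enumeration primitives.

These compose the brute-force oracles in :mod:`ontosim.synth_fixtures`
(explicit path enumeration, no dynamic programming) into full term-pair
similarities, so every measure in the package can be cross-checked on small
graphs without sharing any traversal code with the implementation under test.
"""

import math

from ontosim.synth_fixtures import (
    oracle_contributions,
    oracle_depth,
    oracle_hcd_set,
    oracle_lca_set,
    oracle_paths_up,
    oracle_sv,
)
from ontosim.term_semantics import DEFAULT_WEIGHTS


def _ratio(num, den, identity):
    if den == 0.0:
        return 1.0 if identity else 0.0
    return num / den


def o_baseline(g, a, b, w=DEFAULT_WEIGHTS, root_zeroed=True):
    if g.resolve(a) == g.resolve(b):
        return 1.0
    sa = oracle_contributions(g, a, "up", w, root_zeroed)
    sb = oracle_contributions(g, b, "up", w, root_zeroed)
    shared = set(sa) & set(sb)
    return _ratio(
        sum(sa[t] + sb[t] for t in shared),
        sum(sa.values()) + sum(sb.values()),
        identity=False,
    )


def o_wang(g, a, b, w=DEFAULT_WEIGHTS):
    return o_baseline(g, a, b, w, root_zeroed=False)


def o_pick_lca(g, a, b, w=DEFAULT_WEIGHTS):
    cands = oracle_lca_set(g, a, b)
    return min(cands, key=lambda t: (-oracle_sv(g, t, "max_path", w), t))


def o_lca_sim(g, a, b, w=DEFAULT_WEIGHTS):
    a, b = g.resolve(a), g.resolve(b)
    l = o_pick_lca(g, a, b, w)
    num = 2.0 * oracle_sv(g, l, "max_path", w)
    den = oracle_sv(g, a, "max_path", w) + oracle_sv(g, b, "max_path", w)
    return _ratio(num, den, identity=a == b)


def o_desc(g, a, b, w=DEFAULT_WEIGHTS):
    a, b = g.resolve(a), g.resolve(b)
    hs = oracle_hcd_set(g, a, b)
    if not hs:
        return 0.0
    if a == b:
        return 1.0
    h = min(hs)
    dh = oracle_depth(g, h)
    sa = oracle_contributions(g, a, "down", w, depth_cut=dh - oracle_depth(g, a))
    sb = oracle_contributions(g, b, "down", w, depth_cut=dh - oracle_depth(g, b))
    shared = set(sa) & set(sb)
    return _ratio(
        sum(sa[t] + sb[t] for t in shared),
        sum(sa.values()) + sum(sb.values()),
        identity=False,
    )


def o_gontosim(g, a, b, w=DEFAULT_WEIGHTS):
    if g.resolve(a) == g.resolve(b):
        return 1.0
    return w.U * o_lca_sim(g, a, b, w) + w.L * o_desc(g, a, b, w)


def o_baseline_desc(g, a, b, w=DEFAULT_WEIGHTS):
    if g.resolve(a) == g.resolve(b):
        return 1.0
    return w.U * o_baseline(g, a, b, w) + w.L * o_desc(g, a, b, w)


def o_tanimoto_maps(sa, sb, identity):
    union = set(sa) | set(sb)
    num = sum(min(sa.get(t, 0.0), sb.get(t, 0.0)) for t in union)
    den = sum(max(sa.get(t, 0.0), sb.get(t, 0.0)) for t in union)
    return _ratio(num, den, identity)


def o_tanimoto_baseline(g, a, b, w=DEFAULT_WEIGHTS):
    a, b = g.resolve(a), g.resolve(b)
    return o_tanimoto_maps(
        oracle_contributions(g, a, "up", w),
        oracle_contributions(g, b, "up", w),
        identity=a == b,
    )


def o_tanimoto_gontosim(g, a, b, w=DEFAULT_WEIGHTS):
    a, b = g.resolve(a), g.resolve(b)
    if a == b:
        return 1.0
    up = o_tanimoto_baseline(g, a, b, w)
    hs = oracle_hcd_set(g, a, b)
    if not hs:
        down = 0.0
    else:
        h = min(hs)
        dh = oracle_depth(g, h)
        down = o_tanimoto_maps(
            oracle_contributions(g, a, "down", w, depth_cut=dh - oracle_depth(g, a)),
            oracle_contributions(g, b, "down", w, depth_cut=dh - oracle_depth(g, b)),
            identity=False,
        )
    return w.U * up + w.L * down


def o_wu_palmer(g, a, b):
    a, b = g.resolve(a), g.resolve(b)
    if a == b:
        return 1.0

    def updist(t):
        # shortest distance from t to each ancestor, via enumerated root paths
        d = {}
        for p in oracle_paths_up(g, t):
            for i, (n, _) in enumerate(p):
                d[n] = min(d.get(n, i), i)
        return d

    da, db = updist(a), updist(b)
    best = 0.0
    for t in set(da) & set(db):
        d3 = oracle_depth(g, t, longest=False)
        den = da[t] + db[t] + 2.0 * d3
        if den > 0:
            best = max(best, 2.0 * d3 / den)
    return best


def o_ic_counts(g, gene_sets):
    """Annotation-frequency counts using path-enumerated ancestor closures."""
    counts = {}
    for gs in gene_sets:
        for t in gs.terms:
            t = g.resolve(t)
            closure = {n for p in oracle_paths_up(g, t) for n, _ in p}
            for u in closure:
                counts[u] = counts.get(u, 0) + 1
    return counts


def o_resnik(g, gene_sets, a, b):
    counts = o_ic_counts(g, gene_sets)
    a, b = g.resolve(a), g.resolve(b)
    root = g.root_of(a)
    total = counts[root]
    anc = lambda t: {n for p in oracle_paths_up(g, t) for n, _ in p}  # noqa: E731
    best = 0.0
    for t in anc(a) & anc(b):
        if counts.get(t, 0) > 0:
            best = max(best, -math.log(counts[t] / total))
    return best


def o_lin(g, gene_sets, a, b):
    counts = o_ic_counts(g, gene_sets)
    a, b = g.resolve(a), g.resolve(b)
    root = g.root_of(a)
    total = counts[root]

    def ic(t):
        n = counts.get(t, 0)
        return math.inf if n == 0 else -math.log(n / total)

    ia, ib = ic(a), ic(b)
    if not (math.isfinite(ia) and math.isfinite(ib)) or ia + ib == 0:
        return 0.0
    return 2.0 * o_resnik(g, gene_sets, a, b) / (ia + ib)


#: name -> oracle callable(g, a, b) for the IC-free registered measures
ORACLE_MEASURES = {
    "baseline": o_baseline,
    "wang": o_wang,
    "baseline_lca": o_lca_sim,
    "gontosim": o_gontosim,
    "baseline_desc": o_baseline_desc,
    "tanimoto_baseline": o_tanimoto_baseline,
    "tanimoto_gontosim": o_tanimoto_gontosim,
    "wu_palmer": lambda g, a, b, w=DEFAULT_WEIGHTS: o_wu_palmer(g, a, b),
}
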