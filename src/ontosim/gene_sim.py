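"""Best-Match-Average (BMA) gene similarity and gene-gene similarity matrices.

A gene is represented by its set of GO terms (one aspect).  Term-level
similarity is lifted to genes by best-match averaging: every term is scored
against its best match in the other gene's set, and the matched scores from
both directions are averaged over the total number of terms:

    Sim(G1, G2) = ( sum_i max_j s(go_1i, go_2j) + sum_j max_i s(go_2j, go_1i) )
                  / (m + n)

Term-pair results are memoized per matrix build — enzyme-scale corpora reuse
few distinct term pairs across many genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation_io import GeneAnnotationSet
from .errors import DataError
from .obo_graph import OntologyGraph
from .term_semantics import DEFAULT_WEIGHTS, ICTable, WeightConfig, term_similarity

__all__ = ["SimilarityMatrix", "sim_term_to_set", "sim_genes", "build_matrix"]


@dataclass
class SimilarityMatrix:
    """Symmetric gene-gene similarity matrix with unit diagonal."""

    gene_ids: list[str]
    values: np.ndarray
    measure: str
    aspect: str = ""

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.gene_ids, columns=self.gene_ids)
        df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, measure: str = "", aspect: str = "") -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy(dtype=float), measure, aspect)


class _PairCache:
    """Memoizes term-pair totals; keyed on the unordered term pair.

    Measure, weights and IC table are fixed per instance, matching the
    spec'd key (measure, unordered pair, weight config).
    """

    def __init__(
        self,
        g: OntologyGraph,
        measure: str,
        w: WeightConfig,
        ic: ICTable | None,
        enabled: bool = True,
    ) -> None:
        self.g, self.measure, self.w, self.ic = g, measure, w, ic
        self.enabled = enabled
        self._store: dict[tuple[str, str], float] = {}

    def sim(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if self.enabled and key in self._store:
            return self._store[key]
        v = term_similarity(self.g, key[0], key[1], self.measure, self.w, self.ic).total
        if self.enabled:
            self._store[key] = v
        return v


def sim_term_to_set(
    g: OntologyGraph,
    go: str,
    terms: Iterable[str],
    measure: str = "gontosim",
    w: WeightConfig = DEFAULT_WEIGHTS,
    ic: ICTable | None = None,
    _cache: _PairCache | None = None,
) -> float:
    """Best match: maximum similarity between ``go`` and any member of ``terms``."""
    cache = _cache or _PairCache(g, measure, w, ic)
    terms = list(terms)
    if not terms:
        raise DataError("empty term set")
    return max(cache.sim(go, t) for t in terms)


def sim_genes(
    g: OntologyGraph,
    g1: GeneAnnotationSet,
    g2: GeneAnnotationSet,
    measure: str = "gontosim",
    w: WeightConfig = DEFAULT_WEIGHTS,
    ic: ICTable | None = None,
    _cache: _PairCache | None = None,
) -> float:
    """BMA similarity between two annotated genes."""
    if not g1.terms or not g2.terms:
        raise DataError(
            f"gene with empty term set: {g1.gene_id if not g1.terms else g2.gene_id}"
        )
    cache = _cache or _PairCache(g, measure, w, ic)
    t1, t2 = sorted(g1.terms), sorted(g2.terms)
    fwd = sum(max(cache.sim(a, b) for b in t2) for a in t1)
    rev = sum(max(cache.sim(b, a) for a in t1) for b in t2)
    return (fwd + rev) / (len(t1) + len(t2))


def build_matrix(
    g: OntologyGraph,
    gene_sets: Sequence[GeneAnnotationSet],
    measure: str = "gontosim",
    w: WeightConfig = DEFAULT_WEIGHTS,
    ic: ICTable | None = None,
    use_cache: bool = True,
) -> SimilarityMatrix:
    """All-pairs BMA similarity matrix (symmetric, unit diagonal).

    Each unordered gene pair is computed once and mirrored; term-pair
    similarities are shared across gene pairs through the memo cache
    (``use_cache=False`` recomputes everything — observationally identical).
    """
    n = len(gene_sets)
    ids = [gs.gene_id for gs in gene_sets]
    if len(set(ids)) != n:
        raise DataError("duplicate gene IDs in gene_sets")
    cache = _PairCache(g, measure, w, ic, enabled=use_cache)
    values = np.ones((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            v = sim_genes(g, gene_sets[i], gene_sets[j], measure, w, ic, _cache=cache)
            values[i, j] = values[j, i] = v
    aspect = gene_sets[0].aspect if gene_sets else ""
    return SimilarityMatrix(ids, values, measure, aspect)
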