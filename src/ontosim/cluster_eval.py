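"""Clustering evaluation harness: complete-linkage clustering + extrinsic metrics.

Genes are clustered from a precomputed similarity matrix (distance
``d = 1 - similarity``) with complete-linkage agglomerative clustering, and
the clusters are scored against gold-standard class labels (e.g. the first
digit of an enzyme's EC number) with purity, adjusted Rand index,
Fowlkes-Mallows, normalized mutual information, homogeneity, completeness and
V-measure.

Because real class sizes are highly unbalanced, :func:`sampled_evaluation`
implements the equal-sampling protocol: draw the same number of genes from
each class (without replacement), build the matrix, cluster into k = number
of classes, score; repeat, and report mean ± sd per metric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import (
    adjusted_rand_score,
    completeness_score,
    fowlkes_mallows_score,
    homogeneity_score,
    normalized_mutual_info_score,
    v_measure_score,
)
from sklearn.metrics.cluster import contingency_matrix

from .annotation_io import GeneAnnotationSet
from .errors import DataError
from .gene_sim import SimilarityMatrix, build_matrix
from .obo_graph import OntologyGraph
from .term_semantics import DEFAULT_WEIGHTS, ICTable, WeightConfig

__all__ = [
    "ClusterReport",
    "METRIC_NAMES",
    "cluster",
    "purity",
    "extrinsic_metrics",
    "sampled_evaluation",
]

METRIC_NAMES = (
    "purity",
    "adjusted_rand",
    "fowlkes_mallows",
    "nmi",
    "homogeneity",
    "completeness",
    "v_measure",
)


def cluster(matrix: SimilarityMatrix, k: int) -> np.ndarray:
    """Complete-linkage agglomerative clustering cut at ``k`` clusters.

    Operates on the precomputed distance ``1 - similarity``; deterministic
    given the matrix.
    """
    n = len(matrix.gene_ids)
    if k < 1:
        raise DataError(f"k must be >= 1, got {k}")
    if k > n:
        raise DataError(f"k={k} exceeds number of genes n={n}")
    dist = 1.0 - np.asarray(matrix.values, dtype=float)
    np.fill_diagonal(dist, 0.0)
    model = AgglomerativeClustering(
        n_clusters=k, metric="precomputed", linkage="complete"
    )
    return model.fit_predict(dist)


def purity(true_labels: Sequence, cluster_labels: Sequence) -> float:
    """Fraction of samples in the majority true class of their cluster."""
    c = contingency_matrix(true_labels, cluster_labels)
    return float(c.max(axis=0).sum() / c.sum())


def extrinsic_metrics(true_labels: Sequence, cluster_labels: Sequence) -> dict:
    """Standard extrinsic cluster-quality metrics from the contingency table."""
    t, p = list(true_labels), list(cluster_labels)
    return {
        "purity": purity(t, p),
        "adjusted_rand": float(adjusted_rand_score(t, p)),
        "fowlkes_mallows": float(fowlkes_mallows_score(t, p)),
        "nmi": float(normalized_mutual_info_score(t, p, average_method="arithmetic")),
        "homogeneity": float(homogeneity_score(t, p)),
        "completeness": float(completeness_score(t, p)),
        "v_measure": float(v_measure_score(t, p)),
    }


@dataclass
class ClusterReport:
    """Per-repeat metric values and their mean ± sd under equal sampling."""

    n_clusters: int
    linkage: str
    repeats: int
    samples_per_class: int
    seed: int
    measure: str
    per_repeat: list[dict] = field(default_factory=list)
    summary: dict = field(default_factory=dict)  # metric -> {"mean","sd"}

    def compute_summary(self) -> None:
        self.summary = {}
        for m in METRIC_NAMES:
            vals = np.array([r[m] for r in self.per_repeat], dtype=float)
            self.summary[m] = {
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=0)),
            }

    def to_json(self, path=None) -> str:
        payload = {
            "n_clusters": self.n_clusters,
            "linkage": self.linkage,
            "repeats": self.repeats,
            "samples_per_class": self.samples_per_class,
            "seed": self.seed,
            "measure": self.measure,
            "per_repeat": self.per_repeat,
            "summary": self.summary,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_tsv(self, path) -> None:
        rows = [dict(repeat=i + 1, **r) for i, r in enumerate(self.per_repeat)]
        df = pd.DataFrame(rows, columns=["repeat", *METRIC_NAMES])
        df.loc[len(df)] = ["mean", *(self.summary[m]["mean"] for m in METRIC_NAMES)]
        df.loc[len(df)] = ["sd", *(self.summary[m]["sd"] for m in METRIC_NAMES)]
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def sampled_evaluation(
    g: OntologyGraph,
    gene_sets: Sequence[GeneAnnotationSet],
    labels: dict[str, str],
    measure: str = "gontosim",
    samples_per_class: int = 150,
    repeats: int = 10,
    seed: int = 0,
    w: WeightConfig = DEFAULT_WEIGHTS,
    ic: ICTable | None = None,
) -> ClusterReport:
    """Equal-sampling repeated clustering evaluation.

    Each repeat draws ``samples_per_class`` genes per class without
    replacement (one seeded generator drives all repeats), builds the
    similarity matrix, clusters into k = number of classes with complete
    linkage, and scores against the class labels.
    """
    by_class: dict[str, list[GeneAnnotationSet]] = {}
    for gs in gene_sets:
        if gs.gene_id not in labels:
            raise DataError(f"gene {gs.gene_id} has no class label")
        by_class.setdefault(labels[gs.gene_id], []).append(gs)
    for cls, members in sorted(by_class.items()):
        if len(members) < samples_per_class:
            raise DataError(
                f"class {cls!r} has {len(members)} genes "
                f"< samples_per_class={samples_per_class}"
            )
        members.sort(key=lambda gs: gs.gene_id)
    classes = sorted(by_class)
    k = len(classes)
    rng = np.random.default_rng(seed)
    report = ClusterReport(
        n_clusters=k,
        linkage="complete",
        repeats=repeats,
        samples_per_class=samples_per_class,
        seed=seed,
        measure=measure,
    )
    for _ in range(repeats):
        sample: list[GeneAnnotationSet] = []
        truth: list[str] = []
        for cls in classes:
            idx = rng.choice(len(by_class[cls]), size=samples_per_class, replace=False)
            for i in sorted(idx):
                sample.append(by_class[cls][i])
                truth.append(cls)
        matrix = build_matrix(g, sample, measure=measure, w=w, ic=ic)
        pred = cluster(matrix, k)
        report.per_repeat.append(extrinsic_metrics(truth, pred))
    report.compute_summary()
    return report
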