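"""Clustering evaluation on a synthetic enzyme-class-like corpus.

Generates an ontology with six disjoint class branches, samples 20 genes per
class annotated from their branch (with 20% uniform term-replacement noise to
mimic unreviewed electronic annotations), then runs the equal-sampling
protocol: per repeat, draw the same number of genes from every class, build
the gene-gene similarity matrix, cluster with complete linkage into k = 6,
and score against the true class labels.
"""

from ontosim import sampled_evaluation
from ontosim.synth_fixtures import make_class_annotations, make_class_ontology

g = make_class_ontology(n_classes=6, depth=3, branching=2, seed=0)
gene_sets, labels = make_class_annotations(
    g, n_classes=6, genes_per_class=20, terms_per_gene=3, noise=0.2, seed=1
)

report = sampled_evaluation(
    g, gene_sets, labels, measure="gontosim",
    samples_per_class=10, repeats=5, seed=42,
)

print(f"k={report.n_clusters} clusters, {report.linkage} linkage, "
      f"{report.repeats} repeats x {report.samples_per_class} genes/class\n")
print(f"{'metric':<16}{'mean':>8}{'sd':>8}")
for metric, stats in report.summary.items():
    print(f"{metric:<16}{stats['mean']:>8.4f}{stats['sd']:>8.4f}")

print(
    "\nPurity is the fraction of genes falling in their cluster's majority"
    "\nclass; ARI corrects pair-agreement for chance (1 = perfect recovery,"
    "\n~0 = random). With noiseless annotations all metrics reach 1.0."
)
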