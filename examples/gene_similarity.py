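"""Best-Match-Average similarity between annotated genes.

Represents each gene as a set of ontology terms, lifts term-pair similarity
to gene pairs with best-match averaging, and prints the gene-gene matrix.
"""

import pandas as pd

from ontosim import GeneAnnotationSet, build_matrix, sim_genes
from ontosim.synth_fixtures import TOY, make_toy_ontology

g = make_toy_ontology(include_descendant=True)
A, B, C1, D = TOY["A"], TOY["B"], TOY["C1"], TOY["D"]

genes = [
    GeneAnnotationSet("enzyme1", {A, B}, "MF"),   # both siblings
    GeneAnnotationSet("enzyme2", {A}, "MF"),      # one of them
    GeneAnnotationSet("enzyme3", {C1, D}, "MF"),  # their parent + child
]

print("pairwise BMA (gontosim):")
for i, g1 in enumerate(genes):
    for g2 in genes[i + 1:]:
        s = sim_genes(g, g1, g2)
        print(f"  {g1.gene_id} vs {g2.gene_id}: {s:.4f}")

m = build_matrix(g, genes)
print("\nsimilarity matrix (unit diagonal, symmetric):")
print(pd.DataFrame(m.values, index=m.gene_ids, columns=m.gene_ids).round(4))

print(
    "\nenzyme1 vs enzyme2 scores (1 + sim(B,A) + 1)/3: every term is matched"
    "\nagainst its best counterpart in the other gene, then averaged over all"
    "\nterms of both genes."
)
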