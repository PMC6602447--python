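"""Score genes against patient phenotype terms on a tiny hand-built ontology.

Builds a four-term chain (root <- neuro abnormality <- seizure <- focal
seizure), annotates three genes, and scores each against a patient who
reports "seizure".  Shows how direct, ancestor and descendant matches are
weighted by the patient term's information content.
"""

from hporank.ontology import AnnotationSet, OntologyGraph, OntologyTerm, compute_ic
from hporank.scoring import score_gene

terms = {
    "HP:0000001": OntologyTerm("HP:0000001", "phenotypic abnormality", frozenset()),
    "HP:0000707": OntologyTerm("HP:0000707", "nervous system abnormality",
                               frozenset({"HP:0000001"})),
    "HP:0001250": OntologyTerm("HP:0001250", "seizure",
                               frozenset({"HP:0000707"})),
    "HP:0007359": OntologyTerm("HP:0007359", "focal seizure",
                               frozenset({"HP:0001250"})),
}
graph = OntologyGraph(terms)
ann = AnnotationSet({
    "SCN1A": {"HP:0001250"},   # annotated with the patient's exact term
    "DEPDC5": {"HP:0007359"},  # annotated more specifically
    "MECP2": {"HP:0000707"},   # annotated more generally
    "TTN": {"HP:0000001"},
})
ic = compute_ic(graph, ann)
patient = ["HP:0001250"]

print(f"patient term: HP:0001250 (seizure), IC = {ic['HP:0001250']:.4f} nats\n")
print(f"{'gene':8s} {'match':10s} {'score':>8s}")
for gene in ("SCN1A", "DEPDC5", "MECP2", "TTN"):
    bd = score_gene(graph, ic, gene, ann.gene_to_terms[gene], patient)
    print(f"{gene:8s} {bd.rows[0].match.value:10s} {bd.total:8.4f}")

print("""
The direct match (weight 5) dominates; the gene annotated with a more
specific term gets the ancestor weight 2, the more general one the
descendant weight 0.05, scaled by the patient term's IC.""")
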