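"""End-to-end prioritization: VCF + patient terms -> ranked gene report."""

from __future__ import annotations

from dataclasses import dataclass

from .ontology import AnnotationSet, ICTable, OntologyGraph, compute_ic, parse_obo
from .ranking import RankedGene, attach_variants, rank_genes
from .resources import (FrequencyTable, GeneSet, KnownPathogenicSet,
                        load_gene_annotations)
from .scoring import WeightConfig, score_all_genes
from .variants import (FilterConfig, FilterReport, VariantRecord,
                       apply_filters, apply_inheritance, read_vcf)

__all__ = ["PrioritizationResult", "Knowledge", "prioritize"]


@dataclass
class Knowledge:
    """The loaded reference data: ontology, annotations and IC table."""

    graph: OntologyGraph
    annotations: AnnotationSet
    ic: ICTable

    @classmethod
    def load(cls, obo_path, annotations_path, propagate: bool = True) -> "Knowledge":
        graph = parse_obo(str(obo_path))
        ann, _report = load_gene_annotations(annotations_path, graph)
        return cls(graph=graph, annotations=ann,
                   ic=compute_ic(graph, ann, propagate=propagate))


@dataclass
class PrioritizationResult:
    ranked: list[RankedGene]
    kept_records: list[VariantRecord]
    filter_report: FilterReport


def prioritize(records: list[VariantRecord], patient_terms: list[str],
               knowledge: Knowledge,
               cfg: FilterConfig = FilterConfig(),
               weights: WeightConfig = WeightConfig(),
               frequencies: FrequencyTable | None = None,
               known_pathogenic: KnownPathogenicSet | None = None,
               highlight_sets: list[GeneSet] | None = None,
               ) -> PrioritizationResult:
    """Filter the patient's variants and rank their genes by phenotype match.

    The record-level filters run first, then the mode-of-inheritance rule
    (whose compound-het logic needs the post-filter record set), then every
    gene owning a kept variant is scored against the patient terms and
    competition-ranked.
    """
    kept, report = apply_filters(records, cfg, frequencies, known_pathogenic)
    kept = apply_inheritance(kept, cfg.inheritance,
                             require_homozygous=cfg.require_homozygous)
    candidates = {r.gene for r in kept if r.gene is not None}
    known_genes = frozenset(r.gene for r in kept
                            if r.known_pathogenic and r.gene is not None)
    scores = score_all_genes(knowledge.graph, knowledge.ic,
                             knowledge.annotations.gene_to_terms,
                             candidates, patient_terms, weights,
                             genes_with_known_pathogenic=known_genes)
    ranked = rank_genes(scores)
    highlights = {gs.name: gs.genes for gs in (highlight_sets or [])
                  if gs.role == "highlight"}
    attach_variants(ranked, kept, highlight_sets=highlights)
    return PrioritizationResult(ranked=ranked, kept_records=kept,
                                filter_report=report)
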