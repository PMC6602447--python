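"""IC-weighted phenotype matching between patient HPO terms and genes.

Each patient term is matched against a gene's asserted annotations and
classified as a *direct* hit (the term itself is annotated), an *ancestor*
hit (the patient term is more general than an annotated term) or a
*descendant* hit (more specific).  The term contributes

    w(class) x IC(patient term)

to the gene's phenotype score S_HPO(g); contributions are summed over
patient terms, one contribution (the best class) per term.  Graded weights
for ancestor and descendant hits buffer the score against the natural
variability of clinical phenotyping, where two clinicians may annotate the
same patient at different levels of the ontology.  Genes carrying a variant
already reported pathogenic may additionally receive a fixed bonus
(disabled by default: w_known_pathogenic = 0).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .ontology import ICTable, OntologyGraph

__all__ = [
    "WeightConfig",
    "MatchClass",
    "ScoreBreakdown",
    "PatientProfile",
    "match_class",
    "score_gene",
    "score_all_genes",
    "match_ic_sums",
]


@dataclass(frozen=True)
class WeightConfig:
    """Match-class weights.  Defaults are the tuned operating point
    (direct 5, ancestor 2, descendant 0.05) with the known-pathogenic
    bonus disabled."""

    w_direct: float = 5.0
    w_ancestor: float = 2.0
    w_descendant: float = 0.05
    w_known_pathogenic: float = 0.0

    def __post_init__(self):
        for name in ("w_direct", "w_ancestor", "w_descendant", "w_known_pathogenic"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def of(self, mc: "MatchClass") -> float:
        return {MatchClass.DIRECT: self.w_direct,
                MatchClass.ANCESTOR: self.w_ancestor,
                MatchClass.DESCENDANT: self.w_descendant,
                MatchClass.NONE: 0.0}[mc]


class MatchClass(enum.Enum):
    DIRECT = "direct"
    ANCESTOR = "ancestor"
    DESCENDANT = "descendant"
    NONE = "none"


@dataclass(frozen=True)
class TermContribution:
    term: str
    match: MatchClass
    ic: float
    contribution: float


@dataclass(frozen=True)
class ScoreBreakdown:
    gene: str
    rows: tuple[TermContribution, ...]
    hpo_score: float
    pathogenic_bonus: float

    @property
    def total(self) -> float:
        return self.hpo_score + self.pathogenic_bonus

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "hpo_score": self.hpo_score,
            "pathogenic_bonus": self.pathogenic_bonus,
            "total": self.total,
            "terms": [{"term": r.term, "match": r.match.value, "ic": r.ic,
                       "contribution": r.contribution} for r in self.rows],
        }


class PatientProfile:
    """Resolved patient terms with their ancestor/descendant closures and IC,
    precomputed once so that scoring many candidate genes is cheap."""

    def __init__(self, graph: OntologyGraph, ic: ICTable,
                 patient_terms: Sequence[str]):
        if not patient_terms:
            raise ValueError("patient term list is empty")
        self.graph = graph
        self.ic = ic
        # preserve entry order, drop duplicates after resolution
        seen: dict[str, None] = {}
        for t in patient_terms:
            seen.setdefault(graph.resolve(t), None)
        self.terms: tuple[str, ...] = tuple(seen)
        self.term_ic = {t: ic.get(t, 0.0) or 0.0 for t in self.terms}
        self._anc = {t: graph.ancestors(t) for t in self.terms}
        self._desc = {t: graph.descendants(t) for t in self.terms}

    def classify(self, gene_terms: frozenset[str], t: str) -> MatchClass:
        if t in gene_terms:
            return MatchClass.DIRECT
        if self._desc[t] & gene_terms:
            # the patient term is an ancestor of an annotated term
            return MatchClass.ANCESTOR
        if self._anc[t] & gene_terms:
            return MatchClass.DESCENDANT
        return MatchClass.NONE


def match_class(graph: OntologyGraph, gene_terms: Iterable[str],
                t_patient: str) -> MatchClass:
    """Classify one patient term against a gene's asserted annotations.

    Precedence direct > ancestor > descendant when several hold via
    different gene terms.
    """
    gene_terms = frozenset(gene_terms)
    t = graph.resolve(t_patient)
    if t in gene_terms:
        return MatchClass.DIRECT
    if graph.descendants(t) & gene_terms:
        return MatchClass.ANCESTOR
    if graph.ancestors(t) & gene_terms:
        return MatchClass.DESCENDANT
    return MatchClass.NONE


def score_gene(graph: OntologyGraph, ic: ICTable, gene: str,
               gene_terms: Iterable[str], patient_terms: Sequence[str],
               weights: WeightConfig = WeightConfig(),
               has_known_pathogenic_variant: bool = False,
               profile: PatientProfile | None = None) -> ScoreBreakdown:
    """Score one gene against the patient's terms.

    S_HPO(g) = sum over patient terms t of w(match_class(t, g)) * IC(t).
    A patient term with no IC entry (never annotated under the chosen
    propagation rule) contributes zero.
    """
    if profile is None:
        profile = PatientProfile(graph, ic, patient_terms)
    gene_terms = frozenset(gene_terms)
    rows = []
    total = 0.0
    for t in profile.terms:
        mc = profile.classify(gene_terms, t)
        ic_t = profile.term_ic[t]
        contrib = weights.of(mc) * ic_t
        rows.append(TermContribution(t, mc, ic_t, contrib))
        total += contrib
    bonus = weights.w_known_pathogenic if has_known_pathogenic_variant else 0.0
    return ScoreBreakdown(gene=gene, rows=tuple(rows),
                          hpo_score=total, pathogenic_bonus=bonus)


def score_all_genes(graph: OntologyGraph, ic: ICTable,
                    gene_to_terms: Mapping[str, frozenset[str]],
                    candidate_genes: Iterable[str],
                    patient_terms: Sequence[str],
                    weights: WeightConfig = WeightConfig(),
                    genes_with_known_pathogenic: frozenset[str] = frozenset(),
                    ) -> dict[str, ScoreBreakdown]:
    """Score every candidate gene (genes owning at least one kept variant).

    Unannotated candidates score zero but are retained — dropping them is
    the ranking/benchmark layer's decision, not the scorer's.
    """
    candidates = sorted(set(candidate_genes))
    if not candidates:
        return {}
    profile = PatientProfile(graph, ic, patient_terms)
    out = {}
    for g in candidates:
        out[g] = score_gene(graph, ic, g, gene_to_terms.get(g, frozenset()),
                            patient_terms, weights,
                            has_known_pathogenic_variant=g in genes_with_known_pathogenic,
                            profile=profile)
    return out


def match_ic_sums(profile: PatientProfile,
                  gene_terms: frozenset[str]) -> tuple[float, float, float]:
    """Weight-independent IC sums (direct, ancestor, descendant) for one gene.

    S_HPO = w_direct*d + w_ancestor*a + w_descendant*s, which lets a weight
    sweep re-score genes without re-classifying matches.
    """
    d = a = s = 0.0
    for t in profile.terms:
        mc = profile.classify(gene_terms, t)
        ic_t = profile.term_ic[t]
        if mc is MatchClass.DIRECT:
            d += ic_t
        elif mc is MatchClass.ANCESTOR:
            a += ic_t
        elif mc is MatchClass.DESCENDANT:
            s += ic_t
    return d, a, s
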