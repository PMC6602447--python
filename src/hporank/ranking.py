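"""Tie-aware gene ranking and report output.

Ranks follow competition ("1224") ranking: rank(g) = 1 + number of genes
with a strictly greater score, so genes with the exact same score share the
same rank.  Within a tie the printed order is lexicographic, making reports
byte-deterministic and diffable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .scoring import ScoreBreakdown
from .variants import Severity, VariantRecord

__all__ = ["RankedGene", "rank_genes", "attach_variants", "write_report"]


@dataclass
class RankedGene:
    gene: str
    rank: int
    score: float
    breakdown: ScoreBreakdown | None = None
    variants: list[VariantRecord] = field(default_factory=list)
    flags: dict[str, bool] = field(default_factory=dict)

    @property
    def best_severity(self) -> Severity | None:
        if not self.variants:
            return None
        return max(v.effect_class for v in self.variants)


def rank_genes(scores: dict[str, ScoreBreakdown] | dict[str, float]) -> list[RankedGene]:
    """Competition-rank genes by descending total score."""
    totals: dict[str, float] = {}
    breakdowns: dict[str, ScoreBreakdown] = {}
    for g, s in scores.items():
        if isinstance(s, ScoreBreakdown):
            totals[g] = s.total
            breakdowns[g] = s
        else:
            totals[g] = float(s)
    order = sorted(totals, key=lambda g: (-totals[g], g))
    ranked: list[RankedGene] = []
    rank = 0
    prev_score: float | None = None
    for i, g in enumerate(order):
        if prev_score is None or totals[g] != prev_score:
            rank = i + 1  # 1 + number of strictly better genes
            prev_score = totals[g]
        ranked.append(RankedGene(gene=g, rank=rank, score=totals[g],
                                 breakdown=breakdowns.get(g)))
    return ranked


def attach_variants(ranked: list[RankedGene],
                    records: list[VariantRecord],
                    highlight_sets: dict[str, frozenset[str]] | None = None,
                    ) -> list[RankedGene]:
    """Attach each gene's kept variants (sorted, grouped by severity at
    output time) and highlight-set membership flags."""
    by_gene: dict[str | None, list[VariantRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene, []).append(r)
    for rg in ranked:
        rg.variants = sorted(by_gene.get(rg.gene, []),
                             key=lambda v: (-v.effect_class, v.chrom, v.pos,
                                            v.ref, v.alt))
        for name, genes in (highlight_sets or {}).items():
            rg.flags[name] = rg.gene in genes
    return ranked


def write_report(ranked: list[RankedGene], tsv_path=None, json_path=None,
                 link_templates: dict[str, str] | None = None) -> None:
    """Write the summary TSV and/or the detail JSON.

    ``link_templates`` maps a column name to a URL template with a
    ``{gene}`` placeholder (e.g. an OMIM or GeneCards search URL); links
    are emitted as plain strings, no network access.  Both outputs are
    byte-deterministic for a fixed input; the JSON detail round-trips
    scores exactly (floats serialized via repr).
    """
    flag_names = sorted({name for rg in ranked for name in rg.flags})
    links = dict(sorted((link_templates or {}).items()))
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            cols = (["rank", "gene", "score", "best_severity", "n_variants"]
                    + flag_names + list(links))
            fh.write("\t".join(cols) + "\n")
            for rg in ranked:
                sev = rg.best_severity
                row = [str(rg.rank), rg.gene, format(rg.score, ".10g"),
                       sev.name.lower() if sev is not None else ".",
                       str(len(rg.variants))]
                row += ["1" if rg.flags.get(n) else "0" for n in flag_names]
                row += [tpl.format(gene=rg.gene) for tpl in links.values()]
                fh.write("\t".join(row) + "\n")
    if json_path is not None:
        payload = []
        for rg in ranked:
            payload.append({
                "gene": rg.gene,
                "rank": rg.rank,
                "score": rg.score,
                "flags": dict(sorted(rg.flags.items())),
                "breakdown": rg.breakdown.to_dict() if rg.breakdown else None,
                "variants": [{
                    "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                    "effect": v.effect_class.name.lower(),
                    "genotype": v.genotype.value,
                    "coverage": v.coverage,
                    "af": v.af_db,
                    "known_pathogenic": v.known_pathogenic,
                } for v in rg.variants],
            })
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
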