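"""Spike-in benchmarking and weight-grid optimization.

A benchmark case is a known causative variant (or compound-heterozygous
pair) with the patient's HPO terms.  The causative variant is spiked into a
background exome, the full pipeline runs (filters, inheritance, phenotype
score with the known-pathogenic bonus disabled, competition ranking), and
the rank of the causative gene is recorded, capped at rank 100 — anything
beyond counts as not found.  Aggregates are the cumulative top-k accuracy
curve, the median solved rank and the unsolved fraction.

The weight-grid sweep re-scores every case under each (direct, ancestor,
descendant) weight combination.  Because per-gene match classes do not
depend on the weights, the sweep caches each case's per-gene IC sums once
and re-scores combinations by a dot product.  No winner is declared
automatically; the table is for inspection.
"""

from __future__ import annotations

import json
import logging
import statistics
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .ontology import AnnotationSet, ICTable, OntologyGraph
from .ranking import RankedGene, rank_genes
from .resources import FrequencyTable, KnownPathogenicSet, normalize_variant
from .scoring import PatientProfile, WeightConfig, match_ic_sums, score_all_genes
from .variants import (FilterConfig, Genotype, VariantRecord, apply_filters,
                       apply_inheritance, classify_effect)

logger = logging.getLogger(__name__)

__all__ = ["RANK_CAP", "BenchmarkCase", "BenchmarkResult", "BenchmarkEnv",
           "GridSpec", "load_cases", "spike_in", "evaluate_case",
           "result_from_ranking", "cumulative_accuracy", "weight_grid_search",
           "summarize_results"]

RANK_CAP = 100

_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25}


@dataclass(frozen=True)
class BenchmarkCase:
    case_id: str
    gene: str
    variants: tuple[VariantRecord, ...]  # >=2 entries for compound-het cases
    patient_terms: tuple[str, ...]
    inheritance: str = "any"
    negative_control: bool = False

    def __post_init__(self):
        if len(self.patient_terms) < 2:
            raise ValueError(f"{self.case_id}: cases need at least two HPO terms")


@dataclass(frozen=True)
class BenchmarkResult:
    case_id: str
    rank: int | None          # None when not found or errored
    status: str               # "ranked" | "not_found" | "error"

    @property
    def solved_within(self) -> int | None:
        return self.rank if self.status == "ranked" else None


def load_cases(path) -> list[BenchmarkCase]:
    """Read a JSON case manifest (the fixtures module's format)."""
    with open(path) as fh:
        payload = json.load(fh)
    cases = []
    for entry in payload:
        variants = tuple(
            VariantRecord(
                *normalize_variant(v["chrom"], int(v["pos"]), v["ref"], v["alt"]),
                gene=entry["gene"].upper(),
                effect_class=classify_effect(v.get("effect", "")),
                genotype=Genotype(v["genotype"]),
                coverage=int(v.get("dp", 60)),
            ) for v in entry["variants"])
        cases.append(BenchmarkCase(
            case_id=entry["case_id"], gene=entry["gene"].upper(),
            variants=variants, patient_terms=tuple(entry["hpo_terms"]),
            inheritance=entry.get("inheritance", "any") or "any",
            negative_control=bool(entry.get("negative_control", False))))
    return cases


def spike_in(background: Sequence[VariantRecord],
             case: BenchmarkCase) -> list[VariantRecord]:
    """Insert the case's causative variant(s) into the background exome.

    A background record at the same normalized site is replaced (logged);
    output is coordinate-sorted.
    """
    spike_keys = {v.key for v in case.variants}
    out = []
    for r in background:
        if r.key in spike_keys:
            logger.info("%s: spike replaces existing record at %s:%d",
                        case.case_id, r.chrom, r.pos)
            continue
        out.append(r)
    out.extend(case.variants)
    out.sort(key=lambda r: (_CHROM_ORDER.get(r.chrom, 99), r.pos, r.ref, r.alt))
    return out


@dataclass
class BenchmarkEnv:
    """Everything a case evaluation needs besides the weights."""

    graph: OntologyGraph
    ic: ICTable
    annotations: AnnotationSet
    background: list[VariantRecord]
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    frequencies: FrequencyTable | None = None
    known_pathogenic: KnownPathogenicSet | None = None

    @classmethod
    def from_fixture_dir(cls, fixture_dir, max_af: float = 0.01,
                         min_coverage: int = 8) -> "BenchmarkEnv":
        from pathlib import Path

        from .ontology import compute_ic, parse_obo
        from .resources import (load_frequencies, load_gene_annotations,
                                load_known_pathogenic)
        from .variants import read_vcf

        d = Path(fixture_dir)
        graph = parse_obo(str(d / "ontology.obo"))
        ann, _ = load_gene_annotations(d / "annotations.tsv", graph)
        return cls(
            graph=graph,
            ic=compute_ic(graph, ann),
            annotations=ann,
            background=read_vcf(d / "background.vcf"),
            filter_config=FilterConfig(max_af=max_af, min_coverage=min_coverage),
            frequencies=load_frequencies(d / "frequencies.tsv"),
            known_pathogenic=load_known_pathogenic(d / "known_pathogenic.tsv"),
        )


def result_from_ranking(case_id: str, gene: str, ranked: list[RankedGene],
                        cap: int = RANK_CAP) -> BenchmarkResult:
    """Apply the rank-cap rule: rank > cap (or gene absent) is not found."""
    for rg in ranked:
        if rg.gene == gene:
            if rg.rank > cap:
                return BenchmarkResult(case_id, None, "not_found")
            return BenchmarkResult(case_id, rg.rank, "ranked")
    return BenchmarkResult(case_id, None, "not_found")


def _filtered_records(case: BenchmarkCase, env: BenchmarkEnv) -> list[VariantRecord]:
    records = spike_in(env.background, case)
    cfg = env.filter_config
    kept, _report = apply_filters(records, cfg, env.frequencies,
                                  env.known_pathogenic)
    return apply_inheritance(kept, case.inheritance,
                             require_homozygous=cfg.require_homozygous)


def evaluate_case(case: BenchmarkCase, env: BenchmarkEnv,
                  weights: WeightConfig = WeightConfig()) -> BenchmarkResult:
    """Run the full pipeline for one spiked case and record the causative
    gene's capped competition rank.  Pipeline failures are reported as
    status "error", never conflated with "not_found"."""
    try:
        kept = _filtered_records(case, env)
        candidates = {r.gene for r in kept if r.gene is not None}
        scores = score_all_genes(env.graph, env.ic,
                                 env.annotations.gene_to_terms, candidates,
                                 list(case.patient_terms), weights)
        ranked = rank_genes(scores)
    except Exception:
        logger.exception("%s: pipeline failure", case.case_id)
        return BenchmarkResult(case.case_id, None, "error")
    return result_from_ranking(case.case_id, case.gene, ranked)


# ---------------------------------------------------- cached weight sweeps

@dataclass
class CasePrep:
    """Weight-independent per-case state: candidate genes and their
    (direct, ancestor, descendant) IC sums."""

    case_id: str
    gene: str
    genes: list[str]
    profiles: np.ndarray       # shape (n_genes, 3)
    causative_index: int | None
    errored: bool = False


def prepare_case(case: BenchmarkCase, env: BenchmarkEnv) -> CasePrep:
    try:
        kept = _filtered_records(case, env)
        candidates = sorted({r.gene for r in kept if r.gene is not None})
        profile = PatientProfile(env.graph, env.ic, list(case.patient_terms))
        g2t = env.annotations.gene_to_terms
        rows = [match_ic_sums(profile, g2t.get(g, frozenset()))
                for g in candidates]
        profiles = np.array(rows, dtype=float) if rows else np.zeros((0, 3))
        ci = candidates.index(case.gene) if case.gene in candidates else None
        return CasePrep(case.case_id, case.gene, candidates, profiles, ci)
    except Exception:
        logger.exception("%s: pipeline failure during preparation", case.case_id)
        return CasePrep(case.case_id, case.gene, [], np.zeros((0, 3)), None,
                        errored=True)


def result_for_weights(prep: CasePrep, weights: WeightConfig,
                       cap: int = RANK_CAP) -> BenchmarkResult:
    if prep.errored:
        return BenchmarkResult(prep.case_id, None, "error")
    if prep.causative_index is None:
        return BenchmarkResult(prep.case_id, None, "not_found")
    w = np.array([weights.w_direct, weights.w_ancestor, weights.w_descendant])
    scores = prep.profiles @ w
    rank = 1 + int(np.sum(scores > scores[prep.causative_index]))
    if rank > cap:
        return BenchmarkResult(prep.case_id, None, "not_found")
    return BenchmarkResult(prep.case_id, rank, "ranked")


def cumulative_accuracy(results: Sequence[BenchmarkResult],
                        ks: Sequence[int]) -> dict[int, float]:
    """acc(k) = fraction of cases whose causative gene ranks <= k.

    Errored cases count in the denominator, never the numerator.
    """
    if not results:
        raise ValueError("no benchmark results")
    if any(not 1 <= k <= RANK_CAP for k in ks):
        raise ValueError(f"k values must lie in 1..{RANK_CAP}")
    n = len(results)
    return {k: sum(1 for r in results
                   if r.status == "ranked" and r.rank <= k) / n
            for k in ks}


def summarize_results(results: Sequence[BenchmarkResult]) -> dict[str, float]:
    acc = cumulative_accuracy(results, [1, 10, 20, RANK_CAP])
    solved = [r.rank for r in results if r.status == "ranked"]
    return {
        "acc_top1": acc[1],
        "acc_top10": acc[10],
        "acc_top20": acc[20],
        "acc_top100": acc[RANK_CAP],
        "median_rank": float(statistics.median(solved)) if solved else float("nan"),
        "unsolved_fraction": 1.0 - acc[RANK_CAP],
        "n_errored": float(sum(1 for r in results if r.status == "error")),
    }


@dataclass(frozen=True)
class GridSpec:
    """Candidate weight values for the sweep; the default 7 x 7 x 5 grid
    enumerates 245 combinations."""

    direct: tuple[float, ...] = (0.5, 1, 2, 3, 5, 7, 10)
    ancestor: tuple[float, ...] = (0.05, 0.1, 0.5, 1, 2, 3, 5)
    descendant: tuple[float, ...] = (0.05, 0.1, 0.5, 1, 2)

    @property
    def size(self) -> int:
        return len(self.direct) * len(self.ancestor) * len(self.descendant)

    def combinations(self) -> list[WeightConfig]:
        return [WeightConfig(w_direct=d, w_ancestor=a, w_descendant=s)
                for d, a, s in product(self.direct, self.ancestor,
                                       self.descendant)]


def weight_grid_search(cases: Sequence[BenchmarkCase], env: BenchmarkEnv,
                       grid: GridSpec = GridSpec()) -> pd.DataFrame:
    """Evaluate every weight combination over all cases.

    One row per combination with the accuracy curve points, the median
    solved rank and the unsolved fraction, sorted by acc_top10 descending
    then unsolved fraction ascending.  No winner is declared — choosing an
    operating point is a judgment call left to the analyst.
    """
    combos = grid.combinations()
    if not combos:
        raise ValueError("empty weight grid")
    preps = [prepare_case(c, env) for c in cases]
    rows = []
    for w in combos:
        results = [result_for_weights(p, w) for p in preps]
        summary = summarize_results(results)
        rows.append({"w_direct": w.w_direct, "w_ancestor": w.w_ancestor,
                     "w_descendant": w.w_descendant, **summary})
    df = pd.DataFrame(rows)
    return (df.sort_values(["acc_top10", "unsolved_fraction",
                            "w_direct", "w_ancestor", "w_descendant"],
                           ascending=[False, True, True, True, True])
            .reset_index(drop=True))
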