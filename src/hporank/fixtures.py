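"""Deterministic synthetic inputs: ontology, annotations, exome, cases.

The generator emulates, at desk scale, every input the prioritization
pipeline consumes: a rooted layered phenotype DAG, gene-term annotations, a
single-sample background exome VCF with SnpEff-style ANN fields, a
population allele-frequency sidecar, a known-pathogenic site list, and a
manifest of spike-in benchmark cases.  Each case picks an annotated gene,
takes that gene's terms as the patient phenotype — replacing each term by a
parent with probability ``phenotype_noise`` to model the natural
variability of clinical phenotyping — and emits one or two causative
variants spanning dominant, recessive (homozygous and compound-
heterozygous), X-linked and mitochondrial modes.  Negative-control cases
use genes that carry no annotations at all.

Everything is a pure function of the :class:`FixtureSpec`; the same seed
yields byte-identical files.
"""

from __future__ import annotations

import functools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["FixtureSpec", "FixtureData", "build_fixture_data", "make_ontology",
           "make_annotations", "make_background_vcf", "make_frequencies",
           "make_known_pathogenic", "make_regions", "make_cases", "make_all"]

_CHROMS = [str(i) for i in range(1, 23)] + ["X", "MT"]

_BG_EFFECTS = ["missense_variant", "synonymous_variant", "intron_variant",
               "3_prime_UTR_variant", "frameshift_variant", "stop_gained",
               "splice_donor_variant", "inframe_deletion",
               "upstream_gene_variant"]
_BG_EFFECT_P = [0.35, 0.20, 0.15, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05]

_CASE_EFFECTS = ["frameshift_variant", "stop_gained", "missense_variant",
                 "splice_donor_variant"]

_BASES = "ACGT"


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for the synthetic benchmark (see docs/methods.md)."""

    seed: int = 0
    n_terms: int = 300
    dag_depth: int = 5
    n_genes: int = 250
    terms_per_gene: int = 4
    n_background_variants: int = 2000
    n_cases: int = 50
    n_negative_controls: int = 2
    phenotype_noise: float = 0.2

    def __post_init__(self):
        if self.dag_depth >= self.n_terms:
            raise ValueError("dag_depth must be smaller than n_terms")
        if self.terms_per_gene < 2:
            raise ValueError("terms_per_gene must be >= 2 (cases need >=2 terms)")
        if self.n_negative_controls >= self.n_cases:
            raise ValueError("need at least one solvable case")
        if not 0.0 <= self.phenotype_noise <= 1.0:
            raise ValueError("phenotype_noise must lie in [0,1]")


@dataclass
class CaseVariantSpec:
    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str  # het | hom_alt | hemi
    effect: str
    dp: int


@dataclass
class CaseSpec:
    case_id: str
    gene: str
    inheritance: str
    hpo_terms: list[str]
    variants: list[CaseVariantSpec]
    negative_control: bool = False


@dataclass
class FixtureData:
    spec: FixtureSpec
    term_ids: list[str]
    term_layer: dict[str, int]
    term_parents: dict[str, list[str]]
    gene_names: list[str]
    gene_terms: dict[str, list[str]]            # unannotated genes absent
    gene_location: dict[str, tuple[str, int]]   # gene -> (chrom, window start)
    background: list[dict]                      # VCF row dicts, sorted
    frequencies: dict[tuple, float]
    cases: list[CaseSpec]


def _term_id(i: int) -> str:
    return f"HP:{i:07d}"


@functools.lru_cache(maxsize=8)
def build_fixture_data(spec: FixtureSpec) -> FixtureData:
    rng = np.random.default_rng(spec.seed)

    # --- ontology: root + evenly filled layers, parents from shallower layers
    term_ids = [_term_id(i) for i in range(1, spec.n_terms + 1)]
    root = term_ids[0]
    per_layer = max(1, -(-(spec.n_terms - 1) // spec.dag_depth))  # ceil
    term_layer = {root: 0}
    for j, t in enumerate(term_ids[1:]):
        term_layer[t] = min(spec.dag_depth, 1 + j // per_layer)
    by_layer: dict[int, list[str]] = {}
    for t in term_ids:
        by_layer.setdefault(term_layer[t], []).append(t)
    term_parents: dict[str, list[str]] = {root: []}
    for t in term_ids[1:]:
        shallower = [u for layer in range(term_layer[t])
                     for u in by_layer.get(layer, [])]
        n_par = 2 if (len(shallower) > 1 and rng.random() < 0.3) else 1
        idx = rng.choice(len(shallower), size=n_par, replace=False)
        term_parents[t] = sorted(shallower[i] for i in idx)

    # --- genes: the last n_negative_controls get no annotations
    gene_names = [f"GENE{i:04d}" for i in range(1, spec.n_genes + 1)]
    annotated = gene_names[:spec.n_genes - spec.n_negative_controls]
    deep_terms = [t for t in term_ids if term_layer[t] >= min(2, spec.dag_depth)]
    gene_terms: dict[str, list[str]] = {}
    for g in annotated:
        idx = rng.choice(len(deep_terms), size=min(spec.terms_per_gene,
                                                   len(deep_terms)), replace=False)
        gene_terms[g] = sorted(deep_terms[i] for i in idx)

    # --- genomic placement: round-robin chromosomes, 100 kb windows
    gene_location: dict[str, tuple[str, int]] = {}
    per_chrom_count: dict[str, int] = {}
    for i, g in enumerate(gene_names):
        chrom = _CHROMS[i % len(_CHROMS)]
        k = per_chrom_count.get(chrom, 0)
        per_chrom_count[chrom] = k + 1
        gene_location[g] = (chrom, 1_000_000 + k * 100_000)
    next_pos = {g: loc[1] + 1 for g, loc in gene_location.items()}

    def new_position(gene: str) -> int:
        p = next_pos[gene]
        next_pos[gene] = p + int(rng.integers(50, 150))
        return p

    # --- background exome
    background: list[dict] = []
    frequencies: dict[tuple, float] = {}
    for _ in range(spec.n_background_variants):
        g = gene_names[int(rng.integers(0, spec.n_genes))]
        chrom, _start = gene_location[g]
        pos = new_position(g)
        ref = _BASES[int(rng.integers(0, 4))]
        alt = _BASES[(int(_BASES.index(ref)) + 1 + int(rng.integers(0, 3))) % 4]
        if rng.random() < 0.05:  # small insertion
            alt = alt + _BASES[int(rng.integers(0, 4))]
        effect = _BG_EFFECTS[int(rng.choice(len(_BG_EFFECTS), p=_BG_EFFECT_P))]
        if chrom in ("X", "MT"):
            gt = "1" if rng.random() < 0.9 else "0"
        else:
            u = rng.random()
            gt = "0/1" if u < 0.65 else ("1/1" if u < 0.95 else "./.")
        dp = int(rng.integers(0, 8)) if rng.random() < 0.08 else int(rng.poisson(45))
        background.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                           "gene": g, "effect": effect, "gt": gt, "dp": dp})
        u = rng.random()
        if u < 0.35:
            frequencies[(chrom, pos, ref, alt)] = round(float(rng.uniform(0.02, 0.5)), 4)
        elif u < 0.65:
            frequencies[(chrom, pos, ref, alt)] = round(float(rng.uniform(0.0, 0.005)), 6)
    chrom_order = {c: i for i, c in enumerate(_CHROMS)}
    background.sort(key=lambda r: (chrom_order[r["chrom"]], r["pos"], r["ref"], r["alt"]))

    # --- benchmark cases
    n_solvable = spec.n_cases - spec.n_negative_controls
    n_x = max(0, round(0.10 * n_solvable))
    n_mt = max(0, round(0.10 * n_solvable))
    n_rec = round(0.30 * n_solvable)
    n_any = max(0, round(0.10 * n_solvable))
    n_dom = n_solvable - n_x - n_mt - n_rec - n_any

    auto_pool = [g for g in annotated if gene_location[g][0] not in ("X", "MT")]
    x_pool = [g for g in annotated if gene_location[g][0] == "X"]
    mt_pool = [g for g in annotated if gene_location[g][0] == "MT"]
    n_x, n_mt = min(n_x, len(x_pool)), min(n_mt, len(mt_pool))
    n_dom = n_solvable - n_x - n_mt - n_rec - n_any

    def draw(pool: list[str], n: int) -> list[str]:
        idx = rng.choice(len(pool), size=n, replace=False)
        chosen = [pool[i] for i in sorted(int(i) for i in idx)]
        for g in chosen:
            pool.remove(g)
        return chosen

    plan: list[tuple[str, str]] = []   # (mode, gene)
    plan += [("dominant", g) for g in draw(auto_pool, n_dom)]
    rec_genes = draw(auto_pool, n_rec)
    plan += [("recessive", g) for g in rec_genes]
    plan += [("x_linked", g) for g in draw(x_pool, n_x)]
    plan += [("mitochondrial", g) for g in draw(mt_pool, n_mt)]
    plan += [("any", g) for g in draw(auto_pool, n_any)]

    unannotated = gene_names[spec.n_genes - spec.n_negative_controls:]
    plan += [("any", g) for g in unannotated[:spec.n_negative_controls]]

    def noisy_terms(terms: list[str]) -> list[str]:
        out: dict[str, None] = {}
        tset = set(terms)
        for t in terms:
            if rng.random() < spec.phenotype_noise:
                candidates = [p for p in term_parents[t] if p not in tset]
                if candidates:
                    t = candidates[int(rng.integers(0, len(candidates)))]
            out.setdefault(t, None)
        result = list(out)
        return result if len(result) >= 2 else list(terms)

    def case_variant(gene: str, genotype: str) -> CaseVariantSpec:
        chrom, _ = gene_location[gene]
        pos = new_position(gene)
        ref = _BASES[int(rng.integers(0, 4))]
        alt = _BASES[(int(_BASES.index(ref)) + 1 + int(rng.integers(0, 3))) % 4]
        effect = _CASE_EFFECTS[int(rng.integers(0, len(_CASE_EFFECTS)))]
        return CaseVariantSpec(chrom=chrom, pos=pos, ref=ref, alt=alt,
                               genotype=genotype, effect=effect,
                               dp=60 + int(rng.integers(0, 40)))

    cases: list[CaseSpec] = []
    rec_compound_toggle = False
    for i, (mode, gene) in enumerate(plan, 1):
        negative = gene in unannotated
        if mode == "recessive":
            if rec_compound_toggle:
                variants = [case_variant(gene, "het"), case_variant(gene, "het")]
            else:
                variants = [case_variant(gene, "hom_alt")]
            rec_compound_toggle = not rec_compound_toggle
        elif mode in ("x_linked", "mitochondrial"):
            variants = [case_variant(gene, "hemi")]
        else:
            variants = [case_variant(gene, "het")]
        if negative:
            idx = rng.choice(len(deep_terms), size=spec.terms_per_gene, replace=False)
            terms = sorted(deep_terms[j] for j in idx)
        else:
            terms = noisy_terms(gene_terms[gene])
        # some causative variants are common polymorphisms in the frequency
        # table; the known-pathogenic exemption must keep them
        if rng.random() < 0.15:
            for v in variants:
                frequencies[(v.chrom, v.pos, v.ref, v.alt)] = round(
                    float(rng.uniform(0.05, 0.4)), 4)
        cases.append(CaseSpec(case_id=f"CASE{i:03d}", gene=gene,
                              inheritance=mode, hpo_terms=terms,
                              variants=variants, negative_control=negative))

    return FixtureData(spec=spec, term_ids=term_ids, term_layer=term_layer,
                       term_parents=term_parents, gene_names=gene_names,
                       gene_terms=gene_terms, gene_location=gene_location,
                       background=background, frequencies=frequencies,
                       cases=cases)


# ---------------------------------------------------------------- writers

def make_ontology(spec: FixtureSpec, path) -> None:
    data = build_fixture_data(spec)
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-phenotype\n")
        for t in data.term_ids:
            fh.write(f"\n[Term]\nid: {t}\nname: synthetic phenotype "
                     f"{int(t.split(':')[1])} (layer {data.term_layer[t]})\n")
            for p in data.term_parents[t]:
                fh.write(f"is_a: {p}\n")


def make_annotations(spec: FixtureSpec, path) -> None:
    data = build_fixture_data(spec)
    with open(path, "w") as fh:
        fh.write("gene\thpo_id\n")
        for g in sorted(data.gene_terms):
            for t in data.gene_terms[g]:
                fh.write(f"{g}\t{t}\n")


def make_background_vcf(spec: FixtureSpec, path) -> None:
    data = build_fixture_data(spec)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in _CHROMS:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=ANN,Number=.,Type=String,Description="Functional '
                 'annotations: \'Allele | Annotation | Annotation_Impact | '
                 'Gene_Name\'">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE01\n")
        for r in data.background:
            ann = f"{r['alt']}|{r['effect']}|MODIFIER|{r['gene']}" + "|" * 12
            fh.write(f"{r['chrom']}\t{r['pos']}\t.\t{r['ref']}\t{r['alt']}\t"
                     f"100\tPASS\tANN={ann}\tGT:DP\t{r['gt']}:{r['dp']}\n")


def make_frequencies(spec: FixtureSpec, path) -> None:
    data = build_fixture_data(spec)
    chrom_order = {c: i for i, c in enumerate(_CHROMS)}
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\taf\n")
        for key in sorted(data.frequencies,
                          key=lambda k: (chrom_order[k[0]], k[1], k[2], k[3])):
            fh.write("\t".join(map(str, key)) + f"\t{data.frequencies[key]}\n")


def make_known_pathogenic(spec: FixtureSpec, path) -> None:
    data = build_fixture_data(spec)
    chrom_order = {c: i for i, c in enumerate(_CHROMS)}
    keys = sorted({(v.chrom, v.pos, v.ref, v.alt)
                   for c in data.cases for v in c.variants},
                  key=lambda k: (chrom_order[k[0]], k[1], k[2], k[3]))
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for key in keys:
            fh.write("\t".join(map(str, key)) + "\n")


def make_regions(spec: FixtureSpec, path) -> None:
    with open(path, "w") as fh:
        for c in _CHROMS:
            fh.write(f"{c}\t0\t5000000\n")


def make_cases(spec: FixtureSpec, path) -> None:
    data = build_fixture_data(spec)
    payload = [{
        "case_id": c.case_id,
        "gene": c.gene,
        "inheritance": c.inheritance,
        "negative_control": c.negative_control,
        "hpo_terms": c.hpo_terms,
        "variants": [{"chrom": v.chrom, "pos": v.pos, "ref": v.ref,
                      "alt": v.alt, "genotype": v.genotype,
                      "effect": v.effect, "dp": v.dp} for v in c.variants],
    } for c in data.cases]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def make_all(spec: FixtureSpec, outdir) -> dict[str, Path]:
    """Write the full fixture set into ``outdir`` and return the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ontology": outdir / "ontology.obo",
        "annotations": outdir / "annotations.tsv",
        "background_vcf": outdir / "background.vcf",
        "frequencies": outdir / "frequencies.tsv",
        "known_pathogenic": outdir / "known_pathogenic.tsv",
        "regions": outdir / "regions.bed",
        "cases": outdir / "cases.json",
    }
    make_ontology(spec, paths["ontology"])
    make_annotations(spec, paths["annotations"])
    make_background_vcf(spec, paths["background_vcf"])
    make_frequencies(spec, paths["frequencies"])
    make_known_pathogenic(spec, paths["known_pathogenic"])
    make_regions(spec, paths["regions"])
    make_cases(spec, paths["cases"])
    return paths
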