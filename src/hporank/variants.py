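"""Single-sample VCF reading, effect severity classes and the filter chain.

The filter chain mirrors a clinical exome workflow: restrict to regions and
candidate panels, require adequate coverage, discard common polymorphisms
(except variants already reported pathogenic — those are scored, never
silently removed), optionally require homozygosity and a minimum effect
severity, then apply the suspected mode of inheritance at the gene level.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .resources import (FrequencyTable, GeneSet, KnownPathogenicSet,
                        RegionSet, normalize_chrom, normalize_variant)

logger = logging.getLogger(__name__)

__all__ = [
    "Severity",
    "Genotype",
    "VariantRecord",
    "FilterConfig",
    "FilterReport",
    "VcfError",
    "classify_effect",
    "read_vcf",
    "write_vcf",
    "write_variants_tsv",
    "apply_filters",
    "apply_inheritance",
    "load_effect_table",
]


class VcfError(ValueError):
    pass


class Severity(enum.IntEnum):
    """Predicted-effect severity classes, most severe first.

    Classes group variants for display and optional filtering; they carry no
    weight in the phenotype score.
    """

    UNKNOWN = 0
    NONCODING_INTRAGENIC = 1
    SYNONYMOUS = 2
    INFRAME_INDEL = 3
    MISSENSE = 4
    SPLICE_SITE = 5
    STOP_GAIN = 6
    FRAMESHIFT = 7


class Genotype(enum.Enum):
    HET = "het"
    HOM_ALT = "hom_alt"
    HEMI = "hemi"
    MISSING = "missing"


# Sequence-Ontology effect tokens -> severity class
_EFFECT_MAP: dict[str, Severity] = {
    "frameshift_variant": Severity.FRAMESHIFT,
    "stop_gained": Severity.STOP_GAIN,
    "stop_lost": Severity.STOP_GAIN,
    "start_lost": Severity.STOP_GAIN,
    "splice_acceptor_variant": Severity.SPLICE_SITE,
    "splice_donor_variant": Severity.SPLICE_SITE,
    "splice_region_variant": Severity.SPLICE_SITE,
    "missense_variant": Severity.MISSENSE,
    "inframe_insertion": Severity.INFRAME_INDEL,
    "inframe_deletion": Severity.INFRAME_INDEL,
    "disruptive_inframe_insertion": Severity.INFRAME_INDEL,
    "disruptive_inframe_deletion": Severity.INFRAME_INDEL,
    "synonymous_variant": Severity.SYNONYMOUS,
    "stop_retained_variant": Severity.SYNONYMOUS,
    "intron_variant": Severity.NONCODING_INTRAGENIC,
    "5_prime_UTR_variant": Severity.NONCODING_INTRAGENIC,
    "3_prime_UTR_variant": Severity.NONCODING_INTRAGENIC,
    "non_coding_transcript_exon_variant": Severity.NONCODING_INTRAGENIC,
}

_HAPLOID_CHROMS = frozenset({"X", "Y", "MT"})


def classify_effect(ann_token: str) -> Severity:
    """Map a Sequence-Ontology effect token to a severity class.

    Multiple ``&``-joined tokens resolve to the most severe; unrecognized
    tokens map to UNKNOWN.  Total function, never raises.
    """
    if not ann_token:
        return Severity.UNKNOWN
    best = Severity.UNKNOWN
    for tok in ann_token.replace(",", "&").split("&"):
        best = max(best, _EFFECT_MAP.get(tok.strip(), Severity.UNKNOWN))
    return best


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based, minimal representation
    ref: str
    alt: str
    gene: str | None = None
    effect_class: Severity = Severity.UNKNOWN
    genotype: Genotype = Genotype.MISSING
    coverage: int | None = None
    af_db: float | None = None
    known_pathogenic: bool = False
    raw: str | None = field(default=None, compare=False, repr=False)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class FilterConfig:
    max_af: float | None = None
    min_coverage: int | None = None
    regions: RegionSet | None = None
    panel: GeneSet | None = None
    require_homozygous: bool = False
    min_severity: Severity | None = None
    inheritance: str = "any"  # dominant | recessive | x_linked | mitochondrial | any

    def __post_init__(self):
        modes = ("dominant", "recessive", "x_linked", "mitochondrial", "any")
        if self.inheritance not in modes:
            raise ValueError(f"unknown inheritance mode {self.inheritance!r}")
        if self.max_af is not None and not 0.0 <= self.max_af <= 1.0:
            raise ValueError("max_af must lie in [0,1]")


# Application order of the record-level filters.
FILTER_ORDER = ("region", "panel", "coverage", "af", "zygosity", "severity")


@dataclass
class FilterReport:
    n_input: int = 0
    n_kept: int = 0
    drops: dict[str, int] = field(default_factory=lambda: {f: 0 for f in FILTER_ORDER})

    def to_json(self) -> str:
        return json.dumps({"input": self.n_input, "kept": self.n_kept,
                           "drops": self.drops}, sort_keys=True)


def load_effect_table(path) -> dict[tuple[str, int, str, str], tuple[str, str]]:
    """Sidecar TSV chrom/pos/ref/alt/gene/effect for VCFs without ANN/CSQ."""
    table = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise VcfError(f"{path}:{lineno}: expected 6 columns")
            if lineno == 1 and not fields[1].isdigit():
                continue  # header
            key = normalize_variant(fields[0], int(fields[1]), fields[2], fields[3])
            table[key] = (fields[4], fields[5])
    return table


def _genotype_for_alt(alleles: Sequence[int], alt_index: int, chrom: str) -> Genotype:
    if not alleles or any(a < 0 for a in alleles):
        return Genotype.MISSING
    count = sum(1 for a in alleles if a == alt_index)
    if count == 0:
        return Genotype.MISSING
    if len(alleles) == 1:
        return Genotype.HEMI if chrom in _HAPLOID_CHROMS else Genotype.HOM_ALT
    if count == len(alleles):
        return Genotype.HOM_ALT
    return Genotype.HET


def _parse_ann(info_val: str, alt: str) -> tuple[str | None, str | None]:
    """SnpEff ANN: Allele|Annotation|Impact|Gene_Name|... one entry per allele."""
    for entry in info_val.split(","):
        fields = entry.split("|")
        if len(fields) >= 4 and fields[0] == alt:
            return (fields[3] or None), (fields[1] or None)
    return None, None


def _csq_layout(vcf) -> tuple[int, int, int] | None:
    """Column indices (allele, consequence, symbol) from the CSQ header line."""
    try:
        desc = vcf.get_header_type("CSQ")["Description"]
    except KeyError:
        return None
    fmt = desc.split("Format:")[-1].strip().strip('"').split("|")
    idx = {name.strip(): i for i, name in enumerate(fmt)}
    try:
        return idx["Allele"], idx["Consequence"], idx["SYMBOL"]
    except KeyError:
        return None


def read_vcf(path, effect_table=None) -> list[VariantRecord]:
    """Read a single-sample VCF into normalized :class:`VariantRecord` s.

    Multi-allelic sites are split into one record per alt allele.  Gene and
    effect annotations are taken from a SnpEff-style ``ANN`` field, a VEP
    ``CSQ`` field, or the sidecar ``effect_table`` keyed by normalized
    variant, in that order.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if len(vcf.samples) != 1:
        raise VcfError(f"{path}: expected exactly one sample, found {len(vcf.samples)}")
    csq = _csq_layout(vcf)
    records: list[VariantRecord] = []
    for v in vcf:
        raw = str(v).rstrip("\n")
        chrom = normalize_chrom(v.CHROM)
        gt = v.genotypes[0]
        alleles = [a for a in gt[:-1]]  # last element is the phasing flag
        try:
            dp_arr = v.format("DP")
        except KeyError:
            dp_arr = None
        if dp_arr is not None and int(dp_arr[0][0]) >= 0:
            coverage = int(dp_arr[0][0])
        else:
            info_dp = v.INFO.get("DP")
            coverage = int(info_dp) if info_dp is not None else None
        for i, alt in enumerate(v.ALT):
            gene, effect_tok = None, None
            ann = v.INFO.get("ANN")
            if ann:
                gene, effect_tok = _parse_ann(str(ann), alt)
            if gene is None and csq is not None:
                val = v.INFO.get("CSQ")
                if val:
                    ai, ci, si = csq
                    for entry in str(val).split(","):
                        f = entry.split("|")
                        if len(f) > max(csq) and f[ai] == alt:
                            gene, effect_tok = (f[si] or None), (f[ci] or None)
                            break
            key = normalize_variant(chrom, v.POS, v.REF, alt)
            if gene is None and effect_table:
                hit = effect_table.get(key)
                if hit:
                    gene, effect_tok = hit
            records.append(VariantRecord(
                chrom=key[0], pos=key[1], ref=key[2], alt=key[3],
                gene=gene.upper() if gene else None,
                effect_class=classify_effect(effect_tok or ""),
                genotype=_genotype_for_alt(alleles, i + 1, chrom),
                coverage=coverage,
                raw=raw,
            ))
    return records


def write_vcf(records: Iterable[VariantRecord], header: str, path) -> None:
    """Pass-through VCF output: each kept record's original line, once."""
    seen = set()
    with open(path, "w") as fh:
        fh.write(header if header.endswith("\n") else header + "\n")
        for r in records:
            if r.raw and r.raw not in seen:
                seen.add(r.raw)
                fh.write(r.raw + "\n")


def write_variants_tsv(records: Iterable[VariantRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tgene\teffect\tgenotype\tcoverage\taf\tknown_pathogenic\n")
        for r in records:
            fh.write("\t".join([
                r.chrom, str(r.pos), r.ref, r.alt, r.gene or ".",
                r.effect_class.name.lower(), r.genotype.value,
                str(r.coverage) if r.coverage is not None else ".",
                f"{r.af_db:.6g}" if r.af_db is not None else ".",
                "1" if r.known_pathogenic else "0",
            ]) + "\n")


def annotate_resources(records: Sequence[VariantRecord],
                       freqs: FrequencyTable | None = None,
                       known: KnownPathogenicSet | None = None,
                       ) -> list[VariantRecord]:
    """Attach database allele frequency and known-pathogenic status."""
    out = []
    for r in records:
        af = freqs.get(r.key) if freqs is not None else None
        kp = (r.key in known) if known is not None else False
        if af != r.af_db or kp != r.known_pathogenic:
            r = replace(r, af_db=af, known_pathogenic=kp)
        out.append(r)
    return out


def apply_filters(records: Sequence[VariantRecord], cfg: FilterConfig,
                  freqs: FrequencyTable | None = None,
                  known: KnownPathogenicSet | None = None,
                  ) -> tuple[list[VariantRecord], FilterReport]:
    """Apply the record-level filter chain in its fixed order.

    A record is kept iff it passes every active filter; the report counts
    each drop against the first filter that rejects it, so
    kept + sum(drops) == input.  Known-pathogenic records are exempt from
    the allele-frequency filter.
    """
    records = annotate_resources(records, freqs, known)
    report = FilterReport(n_input=len(records))
    kept: list[VariantRecord] = []
    for r in records:
        if cfg.regions is not None and not cfg.regions.contains(r.chrom, r.pos):
            report.drops["region"] += 1
            continue
        if cfg.panel is not None and (r.gene is None or r.gene not in cfg.panel):
            report.drops["panel"] += 1
            continue
        if (cfg.min_coverage is not None and r.coverage is not None
                and r.coverage < cfg.min_coverage):
            report.drops["coverage"] += 1
            continue
        if (cfg.max_af is not None and r.af_db is not None
                and r.af_db > cfg.max_af and not r.known_pathogenic):
            report.drops["af"] += 1
            continue
        if cfg.require_homozygous and r.genotype not in (Genotype.HOM_ALT,
                                                         Genotype.HEMI):
            report.drops["zygosity"] += 1
            continue
        if cfg.min_severity is not None and r.effect_class < cfg.min_severity:
            report.drops["severity"] += 1
            continue
        kept.append(r)
    report.n_kept = len(kept)
    return kept, report


def apply_inheritance(records: Sequence[VariantRecord], mode: str,
                      require_homozygous: bool = False) -> list[VariantRecord]:
    """Gene-level mode-of-inheritance filter.

    recessive keeps homozygous records, and heterozygous records only when
    the same gene carries at least two distinct heterozygous variants (a
    compound-heterozygous surrogate; no phasing information is used, so this
    over-calls compound hets).  Must run after the record-level filters —
    the two-het count is over the records that survived them.
    """
    if mode == "any":
        return list(records)
    if mode == "dominant":
        return [r for r in records if r.genotype is not Genotype.MISSING]
    if mode == "mitochondrial":
        return [r for r in records
                if r.chrom == "MT" and r.genotype is not Genotype.MISSING]
    if mode == "x_linked":
        out = []
        for r in records:
            if r.chrom != "X":
                continue
            if r.genotype in (Genotype.HEMI, Genotype.HOM_ALT):
                out.append(r)
            elif r.genotype is Genotype.HET and not require_homozygous:
                out.append(r)
        return out
    if mode == "recessive":
        het_keys_by_gene: dict[str | None, set] = {}
        for r in records:
            if r.genotype is Genotype.HET:
                het_keys_by_gene.setdefault(r.gene, set()).add(r.key)
        out = []
        for r in records:
            if r.genotype in (Genotype.HOM_ALT, Genotype.HEMI):
                out.append(r)
            elif (r.genotype is Genotype.HET and r.gene is not None
                  and len(het_keys_by_gene.get(r.gene, ())) >= 2):
                out.append(r)
        return out
    raise ValueError(f"unknown inheritance mode {mode!r}")
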