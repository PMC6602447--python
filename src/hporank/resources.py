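"""Loaders for the flat-file resources the filter chain and score consume.

Every variant key — in the VCF, the allele-frequency table and the
known-pathogenic list — is normalized to its minimal representation
(shared suffix then prefix trimmed, position advanced) so membership tests
are independent of how a site happened to be written.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable

logger = logging.getLogger(__name__)

__all__ = [
    "ResourceError",
    "LoadReport",
    "normalize_chrom",
    "normalize_variant",
    "KnownPathogenicSet",
    "FrequencyTable",
    "GeneSet",
    "RegionSet",
    "load_gene_annotations",
    "load_known_pathogenic",
    "load_frequencies",
    "load_gene_set",
    "load_regions",
]

VariantKey = tuple[str, int, str, str]


class ResourceError(ValueError):
    pass


@dataclass
class LoadReport:
    rows_read: int = 0
    rows_kept: int = 0
    rows_dropped: int = 0
    reasons: dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str, n: int = 1) -> None:
        self.rows_dropped += n
        self.reasons[reason] = self.reasons.get(reason, 0) + n


def normalize_chrom(chrom: str) -> str:
    """Strip a ``chr`` prefix and map M -> MT so mtDNA naming variants agree."""
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.upper() in ("M", "MT"):
        return "MT"
    return c.upper() if c.upper() in ("X", "Y") else c


def normalize_variant(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Minimal representation: uppercase alleles, trim shared suffix then
    shared prefix (advancing ``pos``), leaving at least one base each."""
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return normalize_chrom(chrom), pos, ref, alt


def _data_rows(path, expect_cols: int) -> Iterable[tuple[int, list[str]]]:
    """Yield (lineno, fields) for TSV data rows, skipping an optional header."""
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, 1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and len(row) >= 2 and not _looks_numeric(row[1]):
                # header line (second column of data rows is a position/value)
                continue
            yield lineno, row


def _looks_numeric(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


@dataclass(frozen=True)
class KnownPathogenicSet:
    """Sites reported as pathogenic (a ClinVar-style extract)."""

    entries: frozenset[VariantKey]

    def __contains__(self, key: VariantKey) -> bool:
        return normalize_variant(*key) in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class FrequencyTable:
    """Population allele frequencies (1000G/ExAC-style polymorphism table)."""

    af: dict[VariantKey, float]

    def get(self, key: VariantKey) -> float | None:
        return self.af.get(normalize_variant(*key))

    def __len__(self) -> int:
        return len(self.af)


@dataclass(frozen=True)
class GeneSet:
    """A named list of gene symbols: a restriction panel or a highlight set."""

    name: str
    genes: frozenset[str]
    role: str = "panel_restrict"  # or "highlight"

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class RegionSet:
    """Genomic intervals, half-open 0-based as in BED."""

    intervals: frozenset[tuple[str, int, int]]

    def __post_init__(self):
        for c, s, e in self.intervals:
            if s >= e:
                raise ResourceError(f"empty interval {c}:{s}-{e}")

    def contains(self, chrom: str, pos_1based: int) -> bool:
        c = normalize_chrom(chrom)
        p0 = pos_1based - 1
        return any(ci == c and s <= p0 < e for ci, s, e in self.intervals)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for c, s, e in sorted(self.intervals):
                fh.write(f"{c}\t{s}\t{e}\n")

    def __len__(self) -> int:
        return len(self.intervals)


def load_gene_annotations(path, graph) -> tuple["AnnotationSet", LoadReport]:
    """Read a gene<TAB>HPO-term TSV into an :class:`AnnotationSet`.

    Header rows are auto-detected (a data row's second column matches
    ``HP:``-style ids).  Rows whose term is unknown to the ontology after
    obsolete-term resolution are dropped and counted in the report.
    """
    from .ontology import AnnotationSet, OntologyError

    report = LoadReport()
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ResourceError(f"{path}:{lineno}: expected >=2 columns")
            gene, term = fields[0].strip(), fields[1].strip()
            if lineno == 1 and (gene.lower() == "gene"
                                or "hpo" in term.lower()
                                or term.lower() in ("term", "term_id", "id")):
                continue  # header
            report.rows_read += 1
            pairs.append((gene, term))
    ann, n_dropped = AnnotationSet.from_pairs(graph, pairs)
    if n_dropped:
        report.drop("unknown_term", n_dropped)
        logger.warning("%s: dropped %d row(s) with unknown terms", path, n_dropped)
    report.rows_kept = report.rows_read - report.rows_dropped
    if ann.total_annotated_genes == 0:
        raise OntologyError("no annotated genes")
    return ann, report


def load_known_pathogenic(path) -> KnownPathogenicSet:
    entries = set()
    for lineno, row in _data_rows(path, 4):
        if len(row) < 4:
            raise ResourceError(f"{path}:{lineno}: expected chrom/pos/ref/alt")
        try:
            pos = int(row[1])
        except ValueError as e:
            raise ResourceError(f"{path}:{lineno}: malformed position {row[1]!r}") from e
        entries.add(normalize_variant(row[0], pos, row[2], row[3]))
    return KnownPathogenicSet(frozenset(entries))


def load_frequencies(path) -> FrequencyTable:
    af: dict[VariantKey, float] = {}
    for lineno, row in _data_rows(path, 5):
        if len(row) < 5:
            raise ResourceError(f"{path}:{lineno}: expected chrom/pos/ref/alt/af")
        try:
            pos = int(row[1])
            freq = float(row[4])
        except ValueError as e:
            raise ResourceError(f"{path}:{lineno}: malformed row") from e
        if not 0.0 <= freq <= 1.0:
            raise ResourceError(f"{path}:{lineno}: allele frequency {freq} outside [0,1]")
        af[normalize_variant(row[0], pos, row[2], row[3])] = freq
    return FrequencyTable(af)


def load_gene_set(path, role: str = "panel_restrict", name: str | None = None) -> GeneSet:
    """Read a gene list (one symbol per line, or first TSV column)."""
    if role not in ("panel_restrict", "highlight"):
        raise ResourceError(f"unknown gene-set role {role!r}")
    genes = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genes.add(line.split("\t")[0].strip().upper())
    if not genes:
        if role == "panel_restrict":
            raise ResourceError(f"{path}: empty gene panel would filter out everything")
        logger.warning("%s: empty highlight gene set", path)
    import os
    return GeneSet(name=name or os.path.basename(str(path)),
                   genes=frozenset(genes), role=role)


def load_regions(path) -> RegionSet:
    """Read BED3 (0-based half-open) intervals."""
    intervals = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ResourceError(f"{path}:{lineno}: expected BED3")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as e:
                raise ResourceError(f"{path}:{lineno}: malformed coordinates") from e
            intervals.add((normalize_chrom(fields[0]), start, end))
    if not intervals:
        logger.warning("%s: empty region set", path)
    return RegionSet(frozenset(intervals))
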