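import numpy as np
import pytest

from hporank.resources import FrequencyTable, KnownPathogenicSet, RegionSet
from hporank.variants import (FILTER_ORDER, FilterConfig, Genotype, Severity,
                              VariantRecord, VcfError, apply_filters,
                              apply_inheritance, classify_effect, read_vcf)

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=1>
##contig=<ID=X>
##INFO=<ID=ANN,Number=.,Type=String,Description="A|Annotation|Impact|Gene">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def _vcf(tmp_path, body, samples="S1"):
    p = tmp_path / "t.vcf"
    p.write_text(VCF_HEADER.format(samples=samples) + body)
    return p


def rec(**kw):
    base = dict(chrom="1", pos=100, ref="A", alt="T", gene="G1",
                effect_class=Severity.MISSENSE, genotype=Genotype.HET,
                coverage=30)
    base.update(kw)
    return VariantRecord(**base)


class TestClassifyEffect:
    @pytest.mark.parametrize("token, expected", [
        ("stop_gained", Severity.STOP_GAIN),
        ("frameshift_variant", Severity.FRAMESHIFT),
        ("splice_acceptor_variant", Severity.SPLICE_SITE),
        ("missense_variant", Severity.MISSENSE),
        ("synonymous_variant", Severity.SYNONYMOUS),
        ("intron_variant", Severity.NONCODING_INTRAGENIC),
        ("some_future_so_term", Severity.UNKNOWN),
        ("", Severity.UNKNOWN),
    ])
    def test_mapping(self, token, expected):
        assert classify_effect(token) == expected

    def test_most_severe_of_multiple_tokens_wins(self):
        assert classify_effect("intron_variant&stop_gained") == Severity.STOP_GAIN
        assert classify_effect("synonymous_variant&missense_variant") == Severity.MISSENSE

    def test_severity_order_is_total(self):
        assert (Severity.FRAMESHIFT > Severity.STOP_GAIN > Severity.SPLICE_SITE
                > Severity.MISSENSE > Severity.INFRAME_INDEL
                > Severity.SYNONYMOUS > Severity.NONCODING_INTRAGENIC
                > Severity.UNKNOWN)


class TestReadVcf:
    def test_het_with_depth(self, tmp_path):
        recs = read_vcf(_vcf(tmp_path,
            "1\t100\t.\tA\tT\t50\tPASS\tANN=T|missense_variant|MOD|G1\tGT:DP\t0/1:35\n"))
        (r,) = recs
        assert (r.genotype, r.coverage) == (Genotype.HET, 35)
        assert r.gene == "G1" and r.effect_class == Severity.MISSENSE

    def test_multiallelic_site_splits_per_alt(self, tmp_path):
        recs = read_vcf(_vcf(tmp_path,
            "1\t100\t.\tA\tT,G\t50\tPASS\t"
            "ANN=T|missense_variant|MOD|G1,G|stop_gained|MOD|G1\tGT:DP\t1/2:40\n"))
        assert len(recs) == 2
        assert {r.alt for r in recs} == {"T", "G"}
        assert all(r.pos == 100 and r.genotype == Genotype.HET for r in recs)
        assert {r.effect_class for r in recs} == {Severity.MISSENSE,
                                                  Severity.STOP_GAIN}

    def test_haploid_x_call_is_hemizygous(self, tmp_path):
        recs = read_vcf(_vcf(tmp_path,
            "X\t500\t.\tG\tC\t50\tPASS\tANN=C|missense_variant|MOD|GX\tGT:DP\t1:20\n"))
        assert recs[0].genotype == Genotype.HEMI

    def test_unparseable_gt_becomes_missing(self, tmp_path):
        recs = read_vcf(_vcf(tmp_path,
            "1\t100\t.\tA\tT\t50\tPASS\tANN=T|missense_variant|MOD|G1\tGT:DP\t./.:20\n"))
        assert recs[0].genotype == Genotype.MISSING

    def test_multi_sample_vcf_rejected(self, tmp_path):
        p = _vcf(tmp_path,
                 "1\t100\t.\tA\tT\t50\tPASS\t.\tGT\t0/1\t0/1\n",
                 samples="S1\tS2")
        with pytest.raises(VcfError, match="one sample"):
            read_vcf(p)

    def test_sidecar_effect_table(self, tmp_path):
        p = _vcf(tmp_path, "1\t100\t.\tA\tT\t50\tPASS\t.\tGT:DP\t0/1:35\n")
        table = {("1", 100, "A", "T"): ("MYGENE", "stop_gained")}
        (r,) = read_vcf(p, effect_table=table)
        assert r.gene == "MYGENE" and r.effect_class == Severity.STOP_GAIN


class TestApplyFilters:
    def test_af_filter_hand_count(self):
        records = [rec(pos=p) for p in (1, 2, 3, 4)] + [rec(pos=5, af_db=None)]
        freqs = FrequencyTable({("1", 5, "A", "T"): 0.20})
        kept, report = apply_filters(records, FilterConfig(max_af=0.01),
                                     freqs=freqs)
        assert len(kept) == 4
        assert report.drops["af"] == 1

    def test_known_pathogenic_exempt_from_af_filter(self):
        records = [rec()]
        freqs = FrequencyTable({("1", 100, "A", "T"): 0.20})
        known = KnownPathogenicSet(frozenset({("1", 100, "A", "T")}))
        kept, report = apply_filters(records, FilterConfig(max_af=0.01),
                                     freqs=freqs, known=known)
        assert len(kept) == 1 and kept[0].known_pathogenic
        # without the known list the same record is dropped
        kept2, _ = apply_filters(records, FilterConfig(max_af=0.01), freqs=freqs)
        assert kept2 == []

    def test_coverage_boundary_is_greater_equal(self):
        cfg = FilterConfig(min_coverage=10)
        assert apply_filters([rec(coverage=9)], cfg)[0] == []
        assert len(apply_filters([rec(coverage=10)], cfg)[0]) == 1

    def test_region_and_panel_filters(self):
        from hporank.resources import GeneSet
        cfg = FilterConfig(
            regions=RegionSet(frozenset({("1", 0, 150)})),
            panel=GeneSet("p", frozenset({"G1"}), "panel_restrict"))
        kept, report = apply_filters(
            [rec(pos=100), rec(pos=200), rec(pos=120, gene="G2")], cfg)
        assert [r.pos for r in kept] == [100]
        assert report.drops["region"] == 1 and report.drops["panel"] == 1

    def test_zygosity_and_severity(self):
        cfg = FilterConfig(require_homozygous=True,
                           min_severity=Severity.MISSENSE)
        records = [rec(genotype=Genotype.HET),
                   rec(pos=101, genotype=Genotype.HOM_ALT),
                   rec(pos=102, genotype=Genotype.HEMI, chrom="X"),
                   rec(pos=103, genotype=Genotype.HOM_ALT,
                       effect_class=Severity.SYNONYMOUS)]
        kept, report = apply_filters(records, cfg)
        assert [r.pos for r in kept] == [101, 102]  # hemi satisfies homozygosity
        assert report.drops["zygosity"] == 1 and report.drops["severity"] == 1

    def test_drop_accounting_sums_to_input(self):
        rng = np.random.default_rng(3)
        records = [rec(pos=int(p),
                       coverage=int(rng.integers(0, 60)),
                       genotype=Genotype.HET if rng.random() < 0.6
                       else Genotype.HOM_ALT,
                       effect_class=Severity(int(rng.integers(0, 8))))
                   for p in rng.choice(10_000, size=300, replace=False)]
        freqs = FrequencyTable({("1", r.pos, "A", "T"):
                                float(rng.uniform(0, 0.5)) for r in records[::3]})
        cfg = FilterConfig(max_af=0.05, min_coverage=10,
                           require_homozygous=True,
                           min_severity=Severity.SYNONYMOUS)
        kept, report = apply_filters(records, cfg, freqs=freqs)
        assert report.n_kept + sum(report.drops.values()) == report.n_input == 300
        assert set(report.drops) == set(FILTER_ORDER)

    def test_filter_chain_is_monotone(self):
        records = [rec(pos=p, coverage=p % 50) for p in range(1, 200)]
        base_kept, _ = apply_filters(records, FilterConfig())
        tighter, _ = apply_filters(records, FilterConfig(min_coverage=20))
        assert set(r.key for r in tighter) <= set(r.key for r in base_kept)


class TestInheritance:
    @pytest.mark.parametrize("mode, records, expected_pos", [
        # single het in a gene fails recessive
        ("recessive", [rec(genotype=Genotype.HET)], []),
        # two distinct hets in one gene pass (compound-het surrogate)
        ("recessive", [rec(pos=1, genotype=Genotype.HET),
                       rec(pos=2, genotype=Genotype.HET)], [1, 2]),
        # homozygous always passes recessive
        ("recessive", [rec(genotype=Genotype.HOM_ALT)], [100]),
        # two hets in different genes do not rescue each other
        ("recessive", [rec(pos=1, genotype=Genotype.HET),
                       rec(pos=2, gene="G2", genotype=Genotype.HET)], []),
        # dominant: any non-missing genotype passes
        ("dominant", [rec(genotype=Genotype.HET),
                      rec(pos=101, genotype=Genotype.MISSING)], [100]),
        # mitochondrial mode drops autosomal records
        ("mitochondrial", [rec(), rec(pos=5, chrom="MT",
                                      genotype=Genotype.HEMI)], [5]),
        # x-linked keeps only X records
        ("x_linked", [rec(), rec(pos=7, chrom="X", genotype=Genotype.HEMI)], [7]),
        # no-op mode
        ("any", [rec(), rec(pos=101)], [100, 101]),
    ])
    def test_mode_table(self, mode, records, expected_pos):
        kept = apply_inheritance(records, mode)
        assert sorted(r.pos for r in kept) == sorted(expected_pos)

    def test_x_linked_het_depends_on_homozygosity_requirement(self):
        het_x = rec(chrom="X", genotype=Genotype.HET)
        assert apply_inheritance([het_x], "x_linked") == [het_x]
        assert apply_inheritance([het_x], "x_linked",
                                 require_homozygous=True) == []

    def test_compound_het_rule_runs_after_record_filters(self):
        # one of the two hets fails coverage; the survivor is then a single
        # het and must not pass recessive
        records = [rec(pos=1, genotype=Genotype.HET, coverage=50),
                   rec(pos=2, genotype=Genotype.HET, coverage=3)]
        kept, _ = apply_filters(records, FilterConfig(min_coverage=10))
        assert apply_inheritance(kept, "recessive") == []
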