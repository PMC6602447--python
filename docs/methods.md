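# Methods

## Model

The prioritizer assumes a monogenic disorder: one gene (or one
compound-heterozygous pair of variants in one gene) explains the patient's
phenotype, and that gene — if known to cause disease — carries HPO
annotations that overlap the terms a clinician would assign to the patient.

**Information content.** For a term *t*, IC(t) = −ln(n_genes(t)/N_total),
in nats.  `N_total` is always computed from the loaded annotation file,
never hard-coded, so the score adapts to whatever annotation snapshot is
supplied.  Gene counts use the true-path rule by default (a gene annotated
to *t* also counts for every ancestor of *t*), exposed as
`compute_ic(..., propagate=False)` for the raw counts.  Propagation makes
IC monotone non-increasing towards the root and gives interior terms
well-defined IC for ancestor matches.  The logarithm base is a uniform
scale factor on all scores and cannot change a rank, the only observable
the benchmark uses.

**Matching.** A patient term is classified against a gene's *asserted*
annotations (not their closure): direct if annotated, ancestor if it lies
above an annotated term, descendant if below, with precedence
direct > ancestor > descendant when several hold via different annotated
terms.  Each patient term contributes once — its best class times its own
IC — so genes with many redundant annotations do not accumulate extra
credit, and the IC used is always the *patient* term's: using the
gene-side term's IC would inflate descendant matches against very specific
annotations.  Contributions are summed over patient terms; summation (as
opposed to max or mean) rewards genes matching more of the phenotype,
which is what rank optimization needs.  Both choices are configuration
points of `score_gene` in the sense that the per-term breakdown is
exposed; the defaults are as stated.

**Weights.** Defaults w_direct = 5, w_ancestor = 2, w_descendant = 0.05,
w_known_pathogenic = 0.  Only weight *ratios* matter: scaling all three
match weights by c > 0 scales every score by c and preserves all ranks
(tested).  The known-pathogenic bonus defaults to off so that ranking
reflects phenotype evidence alone; it can be enabled for clinical use
where a ClinVar-style hit should float upward.

**Severity classes.** Predicted effects map onto a fixed total order
(frameshift > stop-gain > splice-site > missense > in-frame indel >
synonymous > non-coding intragenic > unknown).  Classes group and
optionally filter variants; they never enter the score.  Effects come from
SnpEff `ANN` or VEP `CSQ` fields, or a sidecar TSV — this package does not
predict variant effects itself.

## Filter chain

Record-level filters apply in a fixed order (region → panel → coverage →
AF → zygosity → severity); a record is kept iff it passes all active
filters, and the report attributes each drop to the first filter that
rejects it, so kept + Σdrops = input.  Boundary conventions: coverage
keeps DP ≥ min_coverage (records with no DP are kept — absence of evidence
is not treated as low coverage); the AF filter drops af > max_af strictly,
and **known-pathogenic records are exempt** — a reported disease mutation
that is also a common entry in a frequency table must be scored, not
silently discarded.  There is no default AF cutoff; callers state one
explicitly.  Hemizygous calls satisfy the homozygosity requirement (a
single-allele alternate call is functionally homozygous).

The mode-of-inheritance rule is gene-level and runs **after** the
record-level filters: recessive keeps homozygotes plus genes with ≥ 2
distinct heterozygous survivors (a compound-het surrogate; without trio
phasing this over-calls, which is documented and accepted), x_linked keeps
X-chromosome hemi/hom (het only when homozygosity is not required),
mitochondrial keeps MT records.  Running the compound-het count before
record filters would let an already-rejected variant rescue its partner;
the ordering is therefore fixed and tested.  Chromosome names are
normalized (`chr` prefixes stripped, M → MT).

## Benchmark

`spike_in` inserts the case's causative variant(s) into the background
exome (replacing an occupied site, logged) and the full pipeline runs with
the case's inheritance mode.  The causative gene's competition rank is
capped at 100; beyond the cap, or if the gene is absent, the case is *not
found*.  Pipeline errors are a separate status, counted in accuracy
denominators but never conflated with not-found.  Cumulative accuracy
acc(k) is the fraction of cases ranked ≤ k.

The weight grid defaults to direct {0.5, 1, 2, 3, 5, 7, 10} × ancestor
{0.05, 0.1, 0.5, 1, 2, 3, 5} × descendant {0.05, 0.1, 0.5, 1, 2} — 245
combinations.  Match classes do not depend on the weights, so the sweep
computes each case's per-gene (direct, ancestor, descendant) IC sums once
and re-scores combinations by a dot product; a test pins this cached path
to the plain per-case evaluator.  The sweep reports acc(1)/acc(10)/
acc(20)/acc(100), median solved rank and unsolved fraction per row and
declares no winner: the intended use is to inspect the table for an
operating point that ranks causative genes highly *and* keeps the unsolved
rate low.

## Synthetic data

The generator is a pure function of `FixtureSpec`; one seed, byte-identical
files.  Defaults: a 300-term, depth-5 layered DAG (each term has 1–2
parents in shallower layers); 250 genes with 4 annotated terms each drawn
from the deeper layers, of which 2 genes carry no annotations and serve as
negative controls; a 2000-variant single-sample background VCF over
chromosomes 1–22, X and MT with SnpEff-style ANN fields, realistic GT/DP
mixes (haploid calls on X/MT) and an allele-frequency sidecar in which
roughly a third of sites are common polymorphisms; and 50 benchmark cases
(≈40% dominant, 30% recessive split between homozygous and
compound-heterozygous, 10% X-linked, 10% mitochondrial, 10% unspecified).
These sizes are a deliberate desk-scale stand-in for a real HPO snapshot
(tens of thousands of terms, thousands of annotated genes) and a real
exome; the benchmark default filter settings are max_af = 0.01 and
min_coverage = 8.  About 15% of causative variants are also planted in the
frequency table as common polymorphisms so the known-pathogenic AF
exemption is exercised end to end.

**Phenotype noise** models inter-clinician variability as
parent-replacement only: each patient term is, with probability
`phenotype_noise` (default 0.2), replaced by a parent term that is not
itself annotated to the causative gene (falling back to the original term
when no such parent exists).  Clinicians disagree mainly in how *general*
their annotation is, not in which organ system it names, so noise never
injects unrelated terms.  At noise 0 every solvable case ranks first by
construction; at noise 1 every replaced term matches as an ancestor.

What the fixtures do **not** emulate: real genome coordinates and gene
structure, linkage and allele-frequency spectra, annotation depth
heterogeneity (real disease genes carry tens of terms), multi-gene
phenocopies, and ClinVar's curation noise.  Passing the packaged benchmark
therefore demonstrates correctness of the machinery and the expected
qualitative behaviour of the score, not field accuracy on patient exomes.
Negative-control genes score zero yet can still fall inside the rank-100
cap through score-zero ties under competition ranking; they are excluded
from the solvable-case recovery statistic.

## Numerical and degenerate-input choices

Scores are double-precision sums over at most a few dozen terms; ties in
the benchmark arise from structurally identical match profiles and are
exact, so no tolerance is applied in ranking.  Tied genes print in
lexicographic order and reports are byte-deterministic.  Variant keys are
minimal-representation normalized (shared suffix then prefix trimmed)
before any membership test.  Degenerate inputs: an empty candidate set
ranks to an empty report; an annotation file with no usable rows, a
zero-gene IC request, an empty restriction panel and an empty benchmark
result set are errors; an empty highlight set only warns.  Patient terms
unknown to the ontology are errors (a typo should not silently weaken the
phenotype), while terms that resolve via `replaced_by` are accepted with a
log line; annotation rows with unknown terms are dropped and counted.

## Limitations

No trio/family logic, phasing, structural variants or ACMG-style
classification; no effect prediction (annotations are taken as given); no
cross-ontology matching (GO / mammalian-phenotype fusion) or
semantic-similarity measures beyond the three match classes; GRCh37-style
coordinates only.  GO/pathway/expression gene lists participate only as
restriction panels or highlight flags, since their weights cannot be tuned
without phenotype-linked truth data.
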