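"""Apply the clinical filter chain to a synthetic exome.

Generates the packaged synthetic fixture set, reads the background exome
VCF, and applies a polymorphism-frequency cutoff, a coverage floor and a
recessive inheritance model, printing how many variants each filter
removed.
"""

import tempfile

from hporank import fixtures as fx
from hporank.resources import load_frequencies
from hporank.variants import FilterConfig, apply_filters, apply_inheritance, read_vcf

with tempfile.TemporaryDirectory() as tmp:
    paths = fx.make_all(fx.FixtureSpec(seed=0), tmp)
    records = read_vcf(paths["background_vcf"])
    freqs = load_frequencies(paths["frequencies"])

    cfg = FilterConfig(max_af=0.01, min_coverage=8)
    kept, report = apply_filters(records, cfg, freqs=freqs)
    recessive = apply_inheritance(kept, "recessive")

print(f"input variants:          {report.n_input}")
for name, n in report.drops.items():
    print(f"  dropped by {name:9s}  {n}")
print(f"kept after record filters: {report.n_kept}")
print(f"kept under recessive model: {len(recessive)}")
print("""
The AF filter removes common polymorphisms (except known-pathogenic sites),
the coverage filter removes poorly supported calls, and the recessive model
keeps homozygous variants plus genes with at least two heterozygous ones
(a compound-heterozygous surrogate).""")
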