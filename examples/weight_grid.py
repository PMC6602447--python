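"""Sweep the 245-combination weight grid over the packaged benchmark.

Re-runs the spike-in benchmark under every (direct, ancestor, descendant)
weight combination of the default 7 x 7 x 5 grid and prints the
best-performing rows.  No winner is auto-selected: choosing an operating
point that balances high top-10 accuracy against a low unsolved rate is a
judgment call.
"""

import tempfile

from hporank import benchmark as bm
from hporank import fixtures as fx

with tempfile.TemporaryDirectory() as tmp:
    fx.make_all(fx.FixtureSpec(seed=0), tmp)
    env = bm.BenchmarkEnv.from_fixture_dir(tmp)
    cases = bm.load_cases(f"{tmp}/cases.json")
    table = bm.weight_grid_search(cases, env)

print(f"{len(table)} weight combinations evaluated\n")
cols = ["w_direct", "w_ancestor", "w_descendant", "acc_top1", "acc_top10",
        "unsolved_fraction"]
print(table[cols].head(8).to_string(index=False))
print("""
Rows are sorted by top-10 accuracy then unsolved fraction.  Proportional
weight combinations (e.g. 1/0.5/0.5 and 2/1/1) produce identical rank
statistics — only weight ratios matter.""")
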