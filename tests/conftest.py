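from __future__ import annotations

import pytest

from hporank import benchmark as bm
from hporank import fixtures as fx
from oracle_utils import build_graph


@pytest.fixture(scope="session")
def fixture_spec() -> fx.FixtureSpec:
    """The packaged synthetic benchmark conditions."""
    return fx.FixtureSpec(seed=1)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, fixture_spec):
    d = tmp_path_factory.mktemp("fixtures")
    fx.make_all(fixture_spec, d)
    return d


@pytest.fixture(scope="session")
def bench_env(fixture_dir) -> bm.BenchmarkEnv:
    return bm.BenchmarkEnv.from_fixture_dir(fixture_dir)


@pytest.fixture(scope="session")
def bench_cases(fixture_dir) -> list[bm.BenchmarkCase]:
    return bm.load_cases(fixture_dir / "cases.json")


@pytest.fixture()
def chain_graph():
    """root <- A <- B, a minimal is-a chain."""
    return build_graph({"root": set(), "A": {"root"}, "B": {"A"}})


@pytest.fixture()
def diamond_graph():
    """root <- {A, B} <- C."""
    return build_graph({"root": set(), "A": {"root"}, "B": {"root"},
                        "C": {"A", "B"}})
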