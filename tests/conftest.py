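import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def balanced6():
    from phyloqc.treecore import parse_newick
    return parse_newick("((a,b),((c,d),(e,f)));")[0]


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """One fixture bundle shared across the session (deterministic, seed 0)."""
    from phyloqc.synthdata import make_fixture_bundle
    outdir = tmp_path_factory.mktemp("bundle")
    manifest = make_fixture_bundle(outdir, seed=0)
    return outdir, manifest
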