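import pytest

from bsaqtl.config import RunConfig
from bsaqtl.pipeline import run_pipeline
from bsaqtl.simulate import FixtureSpec, write_fixture_set

# permutation count used for in-test pipeline runs; the threshold estimate
# is noisier than with the full 1,000 iterations but the same procedure
TEST_ITERATIONS = 200


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The default synthetic study bundle (120 F8 lines, 15+15 bulks, 23x)."""
    out = tmp_path_factory.mktemp("bundle")
    return write_fixture_set(out, FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def default_run(tmp_path_factory, default_bundle):
    """One full pipeline run over the default bundle."""
    out = tmp_path_factory.mktemp("run")
    cfg = RunConfig.from_yaml(default_bundle.config, n_iterations=TEST_ITERATIONS)
    summary = run_pipeline(cfg, out)
    return default_bundle, cfg, summary, out
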