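import pytest

from cryptorf import PipelineConfig, run_all
from cryptorf.synthetic import FixtureConfig, generate_study


@pytest.fixture(scope="session")
def default_config() -> FixtureConfig:
    return FixtureConfig(seed=0)


@pytest.fixture(scope="session")
def study(default_config):
    """One full synthetic study shared by read-only tests."""
    return generate_study(default_config)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full end-to-end run shared by read-only tests."""
    cfg = PipelineConfig()
    outdir = tmp_path_factory.mktemp("run")
    report, results = run_all(cfg, outdir)
    return report, results, outdir
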