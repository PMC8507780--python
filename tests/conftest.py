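import pytest

from hlaquant.cli import config_from_fixtures
from hlaquant.pipeline import run_pipeline
from hlaquant.synthetic import (GeneratorConfig, generate_experiment,
                                write_fixtures)


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    """Moderate-size study conditions shared across the suite."""
    return GeneratorConfig(n_peptides=1200, n_proteins=1200,
                           n_interactors=400, seed=0)


@pytest.fixture(scope="session")
def experiment(default_config):
    return generate_experiment(default_config)


@pytest.fixture(scope="session")
def fixture_dir(experiment, tmp_path_factory):
    d = tmp_path_factory.mktemp("fixtures")
    write_fixtures(experiment, d)
    return d


@pytest.fixture(scope="session")
def pipeline_run(fixture_dir, tmp_path_factory):
    """One full end-to-end run on the shared synthetic experiment."""
    out = tmp_path_factory.mktemp("results")
    cfg = config_from_fixtures(str(fixture_dir), str(out))
    summary = run_pipeline(cfg)
    return cfg, summary
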