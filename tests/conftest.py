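import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from ssrkit import PipelineConfig, develop_markers
from ssrkit.synthetic_fixtures import make_pipeline_fixture


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_fixture():
    """60 kb planted-truth genome shared by the unit tests."""
    return make_pipeline_fixture(
        genome_length=60_000, n_ssrs=30, n_te=3, n_hairpins=3, seed=1
    )


@pytest.fixture(scope="session")
def small_markers(small_fixture, config):
    return develop_markers([small_fixture.genome], config)
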