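import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from hsp70evo.simulate import fixture_small_family

FIXTURE_DIR = Path(__file__).parent / "data" / "fixture"


@pytest.fixture(scope="session")
def family():
    """The canonical seed-0 simulated family (3 species x 4 lineages)."""
    return fixture_small_family()


@pytest.fixture(scope="session")
def fixture_dir():
    return FIXTURE_DIR


@pytest.fixture()
def family_files(tmp_path, family):
    """Fixture family written to disk as the pipeline's file inputs."""
    return family.to_files(tmp_path / "family")
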