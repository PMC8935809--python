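import numpy as np
import pytest

from nitrenium.chem_io import parse_smiles_string
from nitrenium.config import ScoreConfig
from nitrenium.qm.mock import MockEngine
from nitrenium.scoring import clear_reference_cache


@pytest.fixture(autouse=True)
def _fresh_reference_cache():
    """Engine fingerprints repeat across tests (e.g. every MockEngine);
    never let one test's aniline reference leak into another."""
    clear_reference_cache()
    yield
    clear_reference_cache()


@pytest.fixture
def aniline_record():
    return parse_smiles_string("Nc1ccccc1", "aniline")


@pytest.fixture
def fast_config():
    """Config with a cheap conformer search for mock-engine pipeline tests."""
    return ScoreConfig(min_trials=5, max_trials=10, trials_per_rotatable=5)


@pytest.fixture
def mock_engine():
    """Scripted energies for aniline and o-toluidine neutral/cation pairs.

    Values chosen so that ddE(o-toluidine) = (233.5 - 12.9) - (246.4 - 20.1)
    = -5.7 kcal/mol, mirroring realistic magnitudes.
    """
    return MockEngine(energies={
        "C6H7N1+0": 20.1, "C6H6N1+1": 246.4,     # aniline, nitrenium
        "C7H9N1+0": 12.9, "C7H8N1+1": 233.5,     # o-toluidine
    })


@pytest.fixture
def rng():
    return np.random.default_rng(20220321)
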