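import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

from coalscan.simulate import table1_fixture  # noqa: E402


@pytest.fixture(scope="session")
def fixture_bundle():
    """The bundled identification fixture: scaffold protein, the two
    cysteine peptides, modified forms, observed precursors, and a synthetic
    CoAlated CID spectrum."""
    return table1_fixture(seed=0)


@pytest.fixture(scope="session")
def cys_peptide(fixture_bundle):
    """The Cys149/Cys153-containing Lys-C peptide span (138-159)."""
    return fixture_bundle["spans"][0]


@pytest.fixture(scope="session")
def cys288_peptide(fixture_bundle):
    """The Cys288-containing Lys-C peptide span (269-295)."""
    return fixture_bundle["spans"][1]
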