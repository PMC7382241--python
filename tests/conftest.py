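import numpy as np
import pytest

from ternalyze.synthetic import (
    CoilSpec,
    MockTernarySpec,
    generate_coiled_coil,
    generate_mock_ternary,
)
from ternalyze.structure_io import annotate_roles


@pytest.fixture(scope="session")
def seam_coil():
    return generate_coiled_coil(CoilSpec())


@pytest.fixture(scope="session")
def seam_coil_complex(seam_coil):
    return annotate_roles(seam_coil, {"target": ["A", "B"]})


@pytest.fixture(scope="session")
def mock_ternary():
    return generate_mock_ternary(MockTernarySpec())


@pytest.fixture(scope="session")
def retracted_ternary():
    return generate_mock_ternary(MockTernarySpec(ligand_gap=12.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
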