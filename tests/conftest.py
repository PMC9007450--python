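import numpy as np
import pytest

import cleaveti as ct


@pytest.fixture(scope="session")
def lj_fcc():
    """108-site LJ fcc crystal (reduced units) with its force field."""
    return ct.generate_toy_crystal("lj_fcc", (3, 3, 3), seed=1)


@pytest.fixture(scope="session")
def diatomic():
    """Rock-salt crystal of charged dumbbells (real units)."""
    return ct.generate_toy_crystal("diatomic_molecular", (2, 2, 2), seed=1)


@pytest.fixture(scope="session")
def chain():
    """Crystal of flexible 4-site chains with bonds/angles/dihedral."""
    return ct.generate_toy_crystal("flexible_chain", (2, 2, 2), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
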