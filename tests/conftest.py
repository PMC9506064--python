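import pytest

from localep.params import (
    CellGeometry,
    MembraneParams,
    SubstrateSpec,
    default_cells,
    default_dna,
    default_membrane,
    default_substrates,
)


@pytest.fixture(scope="session")
def membrane() -> MembraneParams:
    return default_membrane()


@pytest.fixture(scope="session")
def substrates() -> dict[str, SubstrateSpec]:
    return default_substrates()


@pytest.fixture(scope="session")
def cells() -> dict[str, CellGeometry]:
    return default_cells()


@pytest.fixture(scope="session")
def dna():
    return default_dna()


@pytest.fixture(scope="session")
def substrate_04(substrates) -> SubstrateSpec:
    return substrates["0.4um"]
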