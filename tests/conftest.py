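import numpy as np
import pytest

from fragnet import SpeciesTraitNetwork, five_species_example


@pytest.fixture
def four_species_net() -> SpeciesTraitNetwork:
    """S=4, N=2: trait A provided by species 1-3, trait B by species 4."""
    return SpeciesTraitNetwork.from_matrix(
        [[1, 0], [1, 0], [1, 0], [0, 1]],
        species_ids=["s1", "s2", "s3", "s4"],
        trait_ids=["A", "B"],
    )


@pytest.fixture
def identity3() -> SpeciesTraitNetwork:
    """3x3 identity: each species carries one unique trait."""
    return SpeciesTraitNetwork.from_matrix(np.eye(3, dtype=int))


@pytest.fixture
def worked_example() -> SpeciesTraitNetwork:
    return five_species_example()
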