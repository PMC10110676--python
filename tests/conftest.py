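import pytest

from ifacemut.sasa import SasaParams
from ifacemut.synthetic import ComplexRecipe, make_study_case, make_toy_complex


@pytest.fixture(scope="session")
def study_case():
    """Full planted study fixture: 24 interface residues, 456 candidates,
    10-member planted shortlist, 14 population variants, 10 replicates."""
    return make_study_case(seed=7)


@pytest.fixture(scope="session")
def toy_complex():
    structure, truth = make_toy_complex(ComplexRecipe())
    return structure, truth


@pytest.fixture(scope="session")
def small_complex():
    """A smaller complex for SASA-heavy tests."""
    recipe = ComplexRecipe(
        n_residues=(12, 30),
        contact_count=6,
        anchor_positions=(2, 5),
        exact5_position=4,
        centroid_region=(11, 25),
    )
    structure, truth = make_toy_complex(recipe)
    return structure, truth


@pytest.fixture(scope="session")
def fast_sasa_params():
    return SasaParams(points_per_atom=196)
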