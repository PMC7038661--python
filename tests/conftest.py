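import numpy as np
import pytest

import oxyr_adapt as oa
from oxyr_adapt import oxyr
from oxyr_adapt.pipeline_stages import DEMO_CONDITIONS, demo_modulons


@pytest.fixture(scope="session")
def modulons():
    return demo_modulons()


@pytest.fixture(scope="session")
def conditions():
    return DEMO_CONDITIONS


@pytest.fixture(scope="session")
def reference_protein():
    return oxyr.synthetic_oxyr_protein()


@pytest.fixture(scope="session")
def reference_cds(reference_protein):
    return oa.back_translate(reference_protein)


@pytest.fixture(scope="session")
def planted_isolates():
    """The natural-isolate substitution multiset planted as genome variants."""
    return [
        oa.PlantedVariant(
            genome_id=f"nat-{i + 1:04d}",
            substitution=oa.MutationRecord.parse(s),
            synonymous_extras=i % 3,
        )
        for i, s in enumerate(oxyr.natural_isolate_substitutions())
    ]


@pytest.fixture(scope="session")
def refset():
    return oa.ConstitutiveReferenceSet(entries=oxyr.constitutive_reference_positions())


@pytest.fixture()
def toy_structures():
    displacement = {5: np.array([2.0, 0.0, 0.0]), 12: np.array([0.0, -1.5, 0.5])}
    reduced, oxidized, _ = oa.simulate_structure(
        30, displacement=displacement, seed=11
    )
    return reduced, oxidized
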