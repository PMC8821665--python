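import numpy as np
import pytest

from axonatlas.synthetic import default_atlas_spec, make_atlas, make_cohort


@pytest.fixture(scope="session")
def atlas_spec():
    return default_atlas_spec()


@pytest.fixture(scope="session")
def atlas(atlas_spec):
    """(ParcellationVolume, StructureOntology, BarrelColumnMap)."""
    return make_atlas(atlas_spec)


@pytest.fixture(scope="session")
def small_cohort(atlas_spec):
    """Three synthetic neurons with analytic truth (fast unit-test cohort)."""
    return make_cohort(n=3, seed=11, atlas_spec=atlas_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
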