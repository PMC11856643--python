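import numpy as np
import pytest
from hypothesis import settings

from cdmcompare import (RaschCML, ThetaGrid, make_taxonomy_qmatrix,
                        simulate_additive)
from cdmcompare.taxonomy import (CHANGE_RULE, DEFAULT_TAXONOMY, DESIGN_PRINCIPLE,
                                 ComponentTaxonomy, QMatrix)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    return ThetaGrid.make()


@pytest.fixture(scope="session")
def q18():
    """18 items x 9 components, full column rank, fixed seed."""
    return make_taxonomy_qmatrix(18, rng_seed=7)


@pytest.fixture(scope="session")
def additive_data(q18):
    """Additive-true responses (600 persons) with known truth block."""
    return simulate_additive(q18, n_persons=600, rng_seed=11)


@pytest.fixture(scope="session")
def rasch_fit(additive_data):
    return RaschCML().fit(additive_data.responses)


@pytest.fixture(scope="session")
def identity_taxonomy():
    """Nine-component taxonomy paired with a 9-item identity Q-matrix."""
    q = QMatrix(items=[f"i{k}" for k in range(1, 10)], taxonomy=DEFAULT_TAXONOMY,
                weights=np.eye(9, dtype=int))
    return q


@pytest.fixture(scope="session")
def two_component_taxonomy():
    return ComponentTaxonomy(component_ids=("R1", "D1"),
                             kinds=(CHANGE_RULE, DESIGN_PRINCIPLE))
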