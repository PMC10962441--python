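import warnings

import pytest

from pvsalps.cohort import CohortSpec, generate_cohort
from pvsalps.phantoms import generate_alps_phantom
from pvsalps.tensor import derive_maps, fit_tensor

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def planted_alps_phantom():
    """Noiseless asymmetric ALPS phantom: right index 1.0, left 2.0."""
    return generate_alps_phantom(
        1.0e-3, 1.0e-3, 1.0e-3, 1.0e-3,
        dxx_proj_left=1.2e-3, dxx_assoc_left=0.8e-3,
        dyy_proj_left=0.5e-3, dzz_assoc_left=0.5e-3,
    )


@pytest.fixture(scope="session")
def planted_alps_maps(planted_alps_phantom):
    tensors = fit_tensor(planted_alps_phantom.acquisition)
    return derive_maps(tensors)


@pytest.fixture(scope="session")
def cohort_200():
    """Seeded 200-subject cohort under default (study) conditions."""
    table, truth = generate_cohort(CohortSpec(n=200, seed=11))
    return table, truth
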