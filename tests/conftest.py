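import numpy as np
import pytest

from scanqc import CohortSpec, make_two_tissue_phantom


@pytest.fixture(scope="session")
def two_tissue():
    """Reference two-tissue phantom: GM N(400, 40), WM N(600, 30)."""
    return make_two_tissue_phantom(mu_gm=400, sigma_gm=40, mu_wm=600, sigma_wm=30,
                                   grid_size=64, seed=0)


@pytest.fixture(scope="session")
def small_spec():
    """A cohort spec small enough for image-level tests."""
    return CohortSpec(n_sites=2, scans_per_site=6, grid_size=32, seed=11,
                      artifact_prevalence=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
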