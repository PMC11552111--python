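import numpy as np
import pytest

from imscore.cohort import (simulate_covariates, simulate_outcomes,
                            simulate_true_scores)
from imscore.phantom import PhantomGeometry


@pytest.fixture(scope="session")
def clean_geometry():
    """Coarse phantom grid with noise and PSF switched off."""
    geo = PhantomGeometry.coarse()
    geo.noise_cv = 0.0
    geo.psf_fwhm = 0.0
    return geo


@pytest.fixture(scope="session")
def coarse_geometry():
    """Coarse phantom grid at default noise/PSF."""
    return PhantomGeometry.coarse()


@pytest.fixture(scope="session")
def small_cohort():
    """Eight fully simulated PET/CT patients (covariates, scores, outcomes)."""
    recs = simulate_covariates(8, seed=11)
    recs = simulate_true_scores(recs, seed=11)
    return simulate_outcomes(recs, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
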