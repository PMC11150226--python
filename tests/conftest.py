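import warnings

import numpy as np
import pytest

from habitatpipe.radiomics import QuantizedRegion, discretize
from habitatpipe.synthetic_cohort import CohortConfig, generate_tumor_volume

warnings.filterwarnings("ignore", category=FutureWarning)


def random_region(rng, shape=None, n_levels=4) -> QuantizedRegion:
    """A small random quantized region with a random (connected-ish) mask."""
    if shape is None:
        shape = tuple(rng.integers(2, 7, size=3))
    vals = rng.integers(0, n_levels * 10, size=shape).astype(float)
    mask = rng.random(shape) < 0.8
    if not mask.any():
        mask[0, 0, 0] = True
    return discretize(vals, mask, n_bins=n_levels)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_patient():
    """One deterministic synthetic patient used across unit tests."""
    return generate_tumor_volume(CohortConfig(n_patients=1), patient_seed=42, responder=True)


@pytest.fixture(scope="session")
def preprocessed_patient(small_patient):
    from habitatpipe.habitat_mapping import entropy_map
    from habitatpipe.imaging_io import normalize_grayscale, resample_isotropic

    vol, mask = resample_isotropic(small_patient.volume, small_patient.mask_rater1)
    norm = normalize_grayscale(vol, mask)
    ent = entropy_map(norm, mask)
    return norm, mask, ent
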