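import numpy as np
import pytest

from avpnorm.phantom import (
    PhantomSpec,
    cylinder_spec,
    generate_cohort,
    generate_phantom,
)

# Normative adult aVP biometry summary means (reference cohort, N = 24;
# volumes in mm^3, ellipticity dimensionless), used for arithmetic
# consistency checks of the summary machinery.
REFERENCE_MEANS = {
    ("volume_mm3", "iOrb"): (172.48, 172.61),  # (left, right)
    ("volume_mm3", "iCan"): (38.82, 39.07),
    ("volume_mm3", "iCran"): (107.73, 107.46),
    ("volume_mm3", "ON"): (319.02, 319.14),
    ("epsilon", "OC"): (0.57, 0.57),
}
# Independently reported left/right averages from the same reference cohort.
REFERENCE_LR_AVERAGES = {
    ("volume_mm3", "iCan"): 38.95,
    ("epsilon", "OC"): 0.57,
}


@pytest.fixture(scope="session")
def default_phantom():
    """The canonical deterministic phantom (one side) with its truth table."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def cohort8():
    """8-subject bilateral cohort with mild jitter, fixed seed."""
    return generate_cohort(8, variability=0.05, seed=42)


@pytest.fixture(scope="session")
def cylinder30():
    """30 mm straight (mildly oblique) circular cylinder, r = 1.5 mm."""
    return generate_phantom(cylinder_spec())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_blob_grid(rng, shape=(16, 12, 16), n_seeds=4):
    """A random nonempty binary grid for round-trip/property tests."""
    grid = np.zeros(shape, dtype=bool)
    for _ in range(n_seeds):
        c = np.array([rng.integers(2, s - 2) for s in shape])
        r = rng.integers(1, 4)
        idx = np.indices(shape)
        grid |= ((idx - c.reshape(3, 1, 1, 1)) ** 2).sum(axis=0) <= r * r
    return grid
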