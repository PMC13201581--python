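import numpy as np
import pytest

from lobeprior.phantom import PhantomSpec, make_cohort, make_phantom
from lobeprior.volume_io import normalize_hu


@pytest.fixture(scope="session")
def phantom48():
    """One 48^3 phantom with lesions: (CTVolume in HU, LabelMap, lesion mask)."""
    return make_phantom(PhantomSpec(seed=1, lesion_count=2))


@pytest.fixture(scope="session")
def phantom48_clean():
    """Lesion-free 48^3 phantom."""
    return make_phantom(PhantomSpec(seed=2))


@pytest.fixture(scope="session")
def cohort6():
    """Six-member cohort at the default variability (HU intensities)."""
    return make_cohort(6, PhantomSpec(seed=3))


@pytest.fixture()
def norm_phantom(phantom48_clean):
    vol, lab, _ = phantom48_clean
    return normalize_hu(vol), lab


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
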