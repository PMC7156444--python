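import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gelquant as gq

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def he_section():
    """A default H&E synthetic section with its ground truth."""
    return gq.generate_section(gq.SectionParams(seed=7))


@pytest.fixture(scope="session")
def he_analysis(he_section):
    image, _truth = he_section
    row, inter = gq.analyze_section(image, "HE", collect=True)
    return row, inter


@pytest.fixture(scope="session")
def ihc_section():
    """An IHC (hematoxylin + DAB) synthetic section at 60% positivity."""
    params = gq.SectionParams(seed=11, stain_mode="IHC", positive_fraction=0.6)
    return gq.generate_section(params)


@pytest.fixture(scope="session")
def ihc_analysis(ihc_section):
    image, _truth = ihc_section
    row, inter = gq.analyze_section(image, "H-DAB", collect=True)
    return row, inter


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
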