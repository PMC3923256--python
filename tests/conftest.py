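import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from simcal import REFERENCE_SCHEME, SimilarityProfile, parse_molecule

settings.register_profile(
    "suite", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def benzene():
    return parse_molecule("c1ccccc1", "benzene")


@pytest.fixture(scope="session")
def ethanol():
    return parse_molecule("CCO", "ethanol")


@pytest.fixture(scope="session")
def pyridine():
    return parse_molecule("c1ccncc1", "pyridine")


def make_profiles(similarities, scheme=REFERENCE_SCHEME, yes_fractions=None):
    """Fabricate similarity profiles with distinct molecule ids."""
    profiles = []
    for i, s in enumerate(similarities):
        prof = SimilarityProfile(
            pair_id=f"p{i:04d}",
            molecule_a_id=f"a{i:04d}",
            molecule_b_id=f"b{i:04d}",
            similarities={scheme: float(s)},
        )
        if yes_fractions is not None:
            prof.yes_fraction = float(yes_fractions[i])
        profiles.append(prof)
    return profiles


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
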