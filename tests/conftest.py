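import dataclasses

import numpy as np
import pytest

from fibroquant.synthgen import SyntheticSpec, generate_synthetic_kidney


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


#: Half-scale synthetic frame used throughout the tests: same morphology
#: proportions as the full-size default, much faster to render and analyze.
SMALL_SPEC = SyntheticSpec(
    height=384, width=512, n_tubules=8, tubule_diameter_range=(30.0, 60.0)
)


@pytest.fixture(scope="session")
def small_spec():
    return SMALL_SPEC


@pytest.fixture(scope="session")
def synthetic_30(small_spec):
    """One 30%-fibrosis synthetic field with tubules, plus its ground truth."""
    spec = dataclasses.replace(small_spec, fibrosis_target_fraction=0.30, seed=42)
    return generate_synthetic_kidney(spec)
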