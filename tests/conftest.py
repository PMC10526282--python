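import numpy as np
import pytest

from brainage2d import (PhantomParams, generate_cohort, pack_cohort)

# a small cubic grid keeps unit tests fast; the phantom shell/ventricle
# geometry is scaled down accordingly
TINY = dict(grid_shape=(16, 16, 16), shell_thickness_at_44=3.0,
            thinning_rate=0.05, ventricle_radius_at_44=2.0,
            ventricle_growth_rate=0.02)


@pytest.fixture(scope="session")
def tiny_params():
    return PhantomParams(seed=3, **TINY)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_params):
    return generate_cohort(tiny_params, n=12)


@pytest.fixture(scope="session")
def tiny_packed(tiny_cohort):
    return pack_cohort(tiny_cohort)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
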