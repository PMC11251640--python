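import datetime as dt

import numpy as np
import pytest
from hypothesis import settings
from shapely.geometry import box

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from hauloutsurvey import (
    HauloutOutline,
    OutlineSpec,
    Terrain,
    make_outline,
)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def square_outline():
    """A 100 m x 100 m (10,000 m^2) rocky outline anchored at the origin."""
    return HauloutOutline(
        site_id="sq", survey_date=dt.date(2019, 9, 1), terrain=Terrain.ROCKY,
        polygon=box(0, 0, 100, 100),
    )


@pytest.fixture
def blob_outline():
    """An irregular ~10,000 m^2 outline."""
    return make_outline(OutlineSpec(shape="blob", area=10_000), seed=7,
                        site_id="blob", terrain=Terrain.SANDY)
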