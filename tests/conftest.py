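import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from portalwss.geometry import apply_splenectomy, build_tree

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: Typical portal-hypertensive vessel dimensions (SI units).
DIAMETERS = {"PV": 0.012, "SMV": 0.010, "SV": 0.012, "LGV": 0.005, "IMV": 0.005}
LENGTHS = {"PV": 0.060, "SMV": 0.080, "SV": 0.100, "LGV": 0.040, "IMV": 0.060}
TORTUOSITIES = {"PV": 1.05, "SMV": 1.1, "SV": 1.3, "LGV": 1.2, "IMV": 1.1}


def make_tree(anatomy_type=1, diameters=None, lengths=None, tortuosities=None, **kw):
    return build_tree(
        {**DIAMETERS, **(diameters or {})},
        {**LENGTHS, **(lengths or {})},
        {**TORTUOSITIES, **(tortuosities or {})},
        anatomy_type=anatomy_type,
        **kw,
    )


@pytest.fixture
def pre_tree():
    return make_tree(anatomy_type=1)


@pytest.fixture
def post_tree(pre_tree):
    return apply_splenectomy(pre_tree)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
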