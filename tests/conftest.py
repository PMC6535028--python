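import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fluvial14c as f14

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def pools():
    return f14.default_pools()


@pytest.fixture(scope="session")
def west_pools(pools):
    wanted = ("active_layer", "holocene_deposits")
    return [p for p in pools if p.name in wanted]


@pytest.fixture(scope="session")
def recent(pools):
    return f14.recent_pool(pools)


def fixed_endmembers(delta_rec=97.0, delta_pp=-383.0, n=20_000):
    """Degenerate (point) endmembers: exact-MH regime of the sampler."""
    rec = f14.SourcePool("recent_production", delta_rec, 1e-9, 1)
    ppc = f14.CompositeEndmember(
        np.full(n, float(delta_pp)), ("fixed",), float(delta_pp), 0.0
    )
    return rec, ppc
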