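import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")

import bgcline as bg


@pytest.fixture(scope="session")
def inv():
    return bg.packaged_fixture()


@pytest.fixture(scope="session")
def lines(inv):
    return {(c.strain, c.cluster_id): bg.assemble_line(c) for c in inv.clusters}
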