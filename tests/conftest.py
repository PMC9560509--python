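import pytest
from hypothesis import HealthCheck, settings

import ompakit as ok

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def reference():
    return ok.load_reference()


@pytest.fixture(scope="session")
def scheme(reference):
    return ok.load_scheme(reference=reference)
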