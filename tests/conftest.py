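import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240103)


@pytest.fixture(scope="session")
def label_text():
    return (
        "Flora of Texas\nTravis County\nQuercus alba L.\n"
        "Moist roadside ditch, elev. 120 m.\nJ. K. Small No. 4521, 12 May 1967"
    )
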