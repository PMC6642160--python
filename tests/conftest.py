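import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=30, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def demo():
    """Synthetic demo study shared across pipeline-level tests."""
    from rccpath.pipeline import generate_demo_dataset
    return generate_demo_dataset(seed=0)


@pytest.fixture(scope="session")
def demo_cfg():
    from rccpath.pipeline import demo_config
    return demo_config(seed=0)


@pytest.fixture(scope="session")
def binary_report(demo, demo_cfg):
    """Trained tumor/normal pipeline, reused by survival-stage tests."""
    from rccpath.pipeline import run_classification
    return run_classification(demo["binary"], demo_cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
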