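import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from metsdx import SubjectRecord

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_record(subject_id="S1", **overrides) -> SubjectRecord:
    """A fully observed, criterion-free subject; override fields as needed."""
    base = dict(
        subject_id=subject_id,
        age=45.0,
        stature_m=1.60,
        body_mass_kg=100.0,
        wc_cm=75.0,
        hc_cm=120.0,
        fm_fraction=0.50,
        sbp=120.0,
        dbp=70.0,
        glucose_mgdl=90.0,
        tg_mgdl=100.0,
        hdl_mgdl=60.0,
    )
    base.update(overrides)
    return SubjectRecord(**base)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def normal_record():
    return make_record()
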