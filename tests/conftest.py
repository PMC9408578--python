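import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lmecg import (
    ConductionFlags,
    ECGFeatureRecord,
    LEADS,
    Lead,
    STDeviationVector,
    Sex,
    default_spec,
    generate_exact,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def build_record(
    elevated=(),
    sex=Sex.MALE,
    margin=0.5,
    st_overrides=None,
    lafb=False,
    rbbb=False,
    lbbb=False,
    hdavb=False,
    qrs_ms=100.0,
    **kwargs,
):
    """Record whose STE lead set is exactly ``elevated`` (at threshold+margin)."""
    from lmecg import ste_threshold

    st = {ld: 0.0 for ld in LEADS}
    for name in elevated:
        ld = Lead(name) if isinstance(name, str) else name
        st[ld] = ste_threshold(ld, sex) + margin
    for name, value in (st_overrides or {}).items():
        ld = Lead(name) if isinstance(name, str) else name
        st[ld] = value
    return ECGFeatureRecord(
        id=kwargs.pop("id", "t-0"),
        sex=sex,
        st=STDeviationVector(st),
        qrs_ms=qrs_ms,
        conduction=ConductionFlags(lafb=lafb, rbbb=rbbb, lbbb=lbbb, hdavb=hdavb),
        **kwargs,
    )


@pytest.fixture(scope="session")
def study_spec():
    return default_spec()


@pytest.fixture(scope="session")
def exact_cohort(study_spec):
    return generate_exact(study_spec, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
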