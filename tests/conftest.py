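import numpy as np
import pytest

from fhrisk.cohort import PatientRecord, derive_flags


def make_record(**overrides) -> PatientRecord:
    """A quiet 60-year-old male baseline record; override fields at will."""
    base = dict(id="T0", age=60, sex="male", ldl_c=2.0, tc=3.8, hdl_c=1.0,
                tg=1.5, therapy_level="none")
    base.update(overrides)
    return PatientRecord(**base)


def record_with_flags(**overrides):
    rec = make_record(**overrides)
    return rec, derive_flags(rec)


@pytest.fixture
def baseline_record():
    return make_record()


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic 200-patient synthetic cohort for fast stage tests."""
    from fhrisk.simulate import default_spec, generate
    return generate(default_spec(n=200, seed=7))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
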