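import datetime as dt

import pytest
from hypothesis import settings

import sclerotype as st

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 200-subject synthetic training-set cohort."""
    return st.generate_cohort(st.GeneratorConfig(seed=20))


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return st.extract_features(small_cohort)


@pytest.fixture(scope="session")
def small_classes(small_cohort):
    return st.resolve_labels(small_cohort.labels)


@pytest.fixture
def toy_events():
    def mk(code, system, y, m, d, sid="T1"):
        return st.DiagnosisEvent(sid, code, st.CodeSystem(system), dt.date(y, m, d))

    return mk
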