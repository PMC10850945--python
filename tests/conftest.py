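import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def baseline_cohort():
    from ctdnatrack.synthetic import fixture_baseline_cohort

    return fixture_baseline_cohort()


@pytest.fixture(scope="session")
def paired_cohort():
    from ctdnatrack.synthetic import fixture_paired_cohort

    return fixture_paired_cohort()


@pytest.fixture(scope="session")
def paired_classified(paired_cohort):
    from ctdnatrack.classify import annotate_cohort

    return annotate_cohort(paired_cohort)


@pytest.fixture(scope="session")
def phasing_fixture():
    from ctdnatrack.synthetic import fixture_phasing_patients

    return fixture_phasing_patients()
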