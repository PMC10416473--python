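import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared across read/clean/describe tests."""
    from pvsignal import synthetic

    config = synthetic.SimConfig(n_cases=2000, seed=11)
    return config, synthetic.generate_cohort(config)


@pytest.fixture(scope="session")
def cohort_dir(small_cohort, tmp_path_factory):
    """The same cohort written out as FAERS-style quarterly files."""
    from pvsignal import synthetic

    _, cohort = small_cohort
    directory = tmp_path_factory.mktemp("faers")
    synthetic.write_cohort(cohort, directory)
    return directory
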