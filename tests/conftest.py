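import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_cohort():
    from ctcohort import default_cohort_spec, generate_cohort

    return generate_cohort(default_cohort_spec(seed=11))


@pytest.fixture(scope="session")
def panel_expression(default_cohort):
    from ctcohort import default_gene_panel, generate_expression

    return generate_expression(default_cohort, default_gene_panel(), seed=12)
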