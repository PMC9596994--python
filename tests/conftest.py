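import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_like_data():
    """One realisation of the study-like synthetic scenario."""
    from quitkinetics import default_scenario, generate

    return generate(default_scenario(), seed=1234)


@pytest.fixture(scope="session")
def study_like_estimates(study_like_data):
    """Cessation-rate fits for every (survey, period) cell of the scenario."""
    from quitkinetics import build_period_rates, fit_all

    data = study_like_data
    periods = [(p.period_start, p.period_end) for p in data.spec.periods]
    plan = []
    for label in sorted(data.prevalence):
        rates = build_period_rates(
            periods, data.prev18[label], data.census, data.mortality
        )
        for r in rates:
            usable = [
                p
                for p in data.prevalence[label]
                if r.period_start <= p.year <= r.period_end and not p.missing
            ]
            if len(usable) >= 4:
                plan.append(
                    (label, (r.period_start, r.period_end), r.lambda_init, r.mu_mort)
                )
    return fit_all(data.prevalence, plan)
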