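import pytest

from dietburden import synthetic as syn
from dietburden.config import ScenarioConfig, default_factors


@pytest.fixture(scope="session")
def truth():
    return syn.default_truth()


@pytest.fixture(scope="session")
def factors():
    return default_factors()


@pytest.fixture(scope="session")
def std_pop():
    return syn.standard_population_2000()


@pytest.fixture(scope="session")
def survey_records(truth):
    """A mid-sized survey: every default wave, 1,500 persons per wave."""
    return syn.generate_intake_survey(
        truth, syn.survey_years_default(), n_per_year=1500, seed=11
    )


@pytest.fixture(scope="session")
def population():
    return syn.default_population([2005, 2010, 2015, 2020, 2025, 2030])


@pytest.fixture(scope="session")
def cancer_counts(truth, population):
    return syn.generate_cancer_counts(truth, population, [2005, 2010, 2015, 2020], seed=11)


@pytest.fixture(scope="session")
def study_effects(truth, factors):
    return syn.generate_all_study_effects(
        truth, factors, k_studies=8, se_range=(0.04, 0.15), seed=11
    )


@pytest.fixture()
def small_scenario():
    return ScenarioConfig(mc={"reps": 400})
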