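import numpy as np
import pytest

from saltshift import (
    BaselineBundle,
    BaselineEpi,
    CostSet,
    SaltReductionModel,
    all_strata,
    generate_baseline,
)


@pytest.fixture(scope="session")
def bundle() -> BaselineBundle:
    """Default synthetic baseline, seed 1."""
    return generate_baseline(1)


@pytest.fixture(scope="session")
def model(bundle) -> SaltReductionModel:
    return SaltReductionModel(bundle)


@pytest.fixture(scope="session")
def fitted(model):
    """Deterministic (expected-value) fit of all eight interventions."""
    return model.fit()


def make_uniform_bundle(chd_inc=0.01, stroke_inc=0.008, chd_cf=0.05,
                        stroke_cf=0.07, bg_mort=0.02, pyld=0.1,
                        healthy_cost=2000.0, population=1000.0):
    """A bundle with identical rates in every stratum (toy worlds)."""
    epi = {}
    costs = {}
    pop = {}
    for key in all_strata():
        epi[key] = BaselineEpi(
            chd_incidence=chd_inc, stroke_incidence=stroke_inc,
            chd_case_fatality=chd_cf, stroke_case_fatality=stroke_cf,
            chd_prevalence=0.05, stroke_prevalence=0.04,
            background_mortality=bg_mort, pyld=pyld)
        costs[key] = CostSet(
            healthy_annual=healthy_cost, chd_first_year=16258.0,
            chd_subsequent=5395.0, stroke_first_year=20553.0,
            stroke_subsequent=5991.0)
        pop[key] = population
    return BaselineBundle(epi=epi, costs=costs, population=pop).validate()


@pytest.fixture()
def uniform_bundle() -> BaselineBundle:
    return make_uniform_bundle()
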