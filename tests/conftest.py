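import numpy as np
import pytest

import sinocea as sc


@pytest.fixture(scope="session")
def us_table():
    return sc.us2016()


@pytest.fixture(scope="session")
def gm_table():
    return sc.synthesize_life_table()


@pytest.fixture(scope="session")
def zero_mortality_table():
    return sc.LifeTable(np.arange(0, 120), np.zeros(120), "zero mortality")


@pytest.fixture(scope="session")
def base_config():
    """Bundled base case with the vendored synthetic US-2016 table."""
    return sc.load_base_case()


@pytest.fixture(scope="session")
def base_model(base_config):
    return sc.MarkovCEA(
        base_config.spec,
        base_config.distributions,
        base_config.wtp,
        base_config.psa_iterations,
    )


@pytest.fixture(scope="session")
def base_results(base_model):
    return base_model.fit()


def make_spec(
    life_table,
    p_eradicate=0.9,
    p_eradicate_b=0.73,
    c_rt_a=50_000.0,
    c_rt_b=12_000.0,
    c_chemo=5_000.0,
    relapse=((1, 3, 0.10), (4, 5, 0.05), (6, 10, 0.01)),
    p_cancer_death=0.3,
    u_no_cancer=0.94,
    u_with_cancer=0.47,
    u_first_year=None,
    c_followup=1_000.0,
    c_palliative=5_000.0,
    start_age=47,
    horizon=30,
    discount_rate=0.03,
):
    """Hand-built two-strategy spec with overridable pieces."""
    return sc.ModelSpec(
        strategy_a=sc.StrategyParams(
            name="A", p_eradicate=p_eradicate, c_radiotherapy=c_rt_a, c_chemo=c_chemo
        ),
        strategy_b=sc.StrategyParams(
            name="B", p_eradicate=p_eradicate_b, c_radiotherapy=c_rt_b, c_chemo=c_chemo
        ),
        disease=sc.DiseaseParams(
            relapse_schedule=tuple(
                sc.RelapseInterval(from_year=f, to_year=t, prob=p) for f, t, p in relapse
            ),
            p_cancer_death=p_cancer_death,
            u_no_cancer=u_no_cancer,
            u_with_cancer=u_with_cancer,
            u_first_year=u_first_year,
            c_followup=c_followup,
            c_palliative=c_palliative,
        ),
        settings=sc.RunSettings(
            start_age=start_age, horizon=horizon, discount_rate=discount_rate
        ),
        life_table=life_table,
    )


@pytest.fixture(scope="session")
def synth_spec(gm_table):
    """Base-case parameters on the synthetic Gompertz-Makeham table."""
    return make_spec(gm_table)
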