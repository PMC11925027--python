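import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vivforecast as vf

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cfg() -> vf.SimulationConfig:
    return vf.default_config()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_710)


def stochastic_config(n_replicates: int = 3, master_seed: int = 7) -> vf.SimulationConfig:
    """A mid-sized fully stochastic scenario (seconds to run).

    Linear-growth TAVR, flat SAVR, the default-style distribution families
    with genuine spread, ramping penetration and a small redo series.
    """
    tavr, savr = vf.synthesize_scenario(
        "linear-growth",
        {"start_year": 2000, "end_year": 2015, "tavr_intercept": 50,
         "tavr_slope": 40, "savr_intercept": 300, "savr_slope": 0},
    )
    cfg = vf.SimulationConfig(
        start_year=2000,
        end_year=2015,
        n_replicates=n_replicates,
        master_seed=master_seed,
        tavr_volumes=tavr,
        savr_volumes=savr,
        age_model=vf.AgeDistribution.discretized_normal(77.0, 7.0),
        risk_mix=vf.RiskMixSchedule(
            (
                vf.RiskMixEntry("TAVR", 2000, 2016, 0.3),
                vf.RiskMixEntry("SAVR", 2000, 2016, 0.85),
            )
        ),
        durability_models={
            "TAVR": vf.DurabilityMixture(
                (vf.MixtureComponent(0.2, 3.0, 1.0), vf.MixtureComponent(0.8, 7.0, 2.0))
            ),
            "SAVR_age_lt_70": vf.DurabilityMixture.single(5.0, 2.0),
            "SAVR_age_ge_70": vf.DurabilityMixture.single(8.0, 2.0),
        },
        survival_models={
            "low": vf.SurvivalDistribution("truncated_normal", 12.0, 4.0),
            "intermediate_high": vf.SurvivalDistribution("truncated_normal", 6.0, 2.0),
        },
        penetration=vf.PenetrationSchedule(
            tavr_failure=((2005, 0.2), (2015, 0.7)),
            savr_failure=((2005, 0.5), (2015, 0.8)),
        ),
        redo_series=vf.RedoSurgerySeries(
            savr_after_savr={y: 5 for y in range(2000, 2016)},
            savr_after_tavr={y: 2 for y in range(2000, 2016)},
        ),
    )
    return cfg.validate()
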