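import numpy as np
import pytest

import vancomst as v
from vancomst.metrics import ErrorTable


@pytest.fixture(scope="session")
def planted_cohort():
    """A planted three-region cohort: episodes, truth and its config."""
    config = v.plant_subgroup_scenario(n_patients=60, seed=101)
    episodes, truth = v.generate_cohort(config)
    return config, episodes, truth


@pytest.fixture(scope="session")
def planted_frames(planted_cohort):
    _, episodes, _ = planted_cohort
    return v.build_cohort_timeframes(episodes)


@pytest.fixture(scope="session")
def planted_registry():
    return v.registry_with_decoys()


@pytest.fixture(scope="session")
def planted_table(planted_registry, planted_frames):
    return ErrorTable(planted_registry, planted_frames)


@pytest.fixture(scope="session")
def default_cohort():
    config = v.SimulationConfig(n_patients=40, seed=7)
    episodes, truth = v.generate_cohort(config)
    return config, episodes, truth


def make_episode(
    dose_times,
    obs,
    *,
    sex="male",
    age=60.0,
    height=175.0,
    weight=80.0,
    creatinine=90.0,
    amount=1000.0,
    tinf=1.0,
    rrt=(),
    icu=None,
    creatinine_points=None,
):
    """Hand-built treatment episode for unit tests."""
    doses = [v.DoseEvent(t, amount, tinf, t) for t in dose_times]
    observations = [v.ConcentrationObservation(t, c) for t, c in obs]
    end = max(dose_times) + 24.0
    series = [
        v.CovariateSeries(
            "creatinine_umol_L",
            creatinine_points if creatinine_points is not None else [(0.0, creatinine)],
            is_lab=True,
        ),
        v.CovariateSeries("weight_kg", [(0.0, weight)], is_lab=False),
    ]
    episode = v.TreatmentEpisode(
        patient=v.PatientRecord("P1", sex, age, height),
        episode_id="P1-e1",
        doses=doses,
        observations=observations,
        covariates=series,
        icu_intervals=[(0.0, end)] if icu is None else list(icu),
        rrt_intervals=list(rrt),
    )
    return v.label_troughs(episode)


@pytest.fixture
def simple_episode():
    return make_episode(
        dose_times=[0, 12, 24, 36, 48, 60, 72, 84, 96],
        obs=[(22.0, 15.0), (46.0, 16.0), (70.0, 17.0), (94.0, 18.0)],
    )
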