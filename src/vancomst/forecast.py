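"""Forecasting the third measured concentration.

A treatment episode qualifies for forecasting assessment when it started in
the ICU, has at least three measured concentrations, the third is a trough,
and no covariate needed for prediction is missing.  The third concentration
is then predicted using only information available by the time of the
second measurement, under five settings:

1. *a priori* with the universally best-performing model (covariates only);
2. *a priori* with the MST-selected model (covariates only);
3. covariates + the first measured concentration (MAP);
4. covariates + the second measured concentration (MAP);
5. covariates + both measured concentrations (MAP).

Doses administered between the second and third measurement are part of the
known prospective schedule and are included in the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import ConcentrationObservation, DoseEvent, TreatmentEpisode
from .covariates import CovariateVector, freeze_covariates
from .metrics import pape, ppe
from .mst import DecisionTree, apply_mst
from .pk import (
    EstimationError,
    IndividualParameters,
    PKModelSpec,
    PredictionError,
    map_estimate,
    predict_concentration,
)


class Setting(str, Enum):
    APRIORI_UBM = "apriori_ubm"
    APRIORI_MST = "apriori_mst"
    WITH_FIRST = "with_first"
    WITH_SECOND = "with_second"
    WITH_BOTH = "with_both"


#: Which observations (1-based) each setting conditions on.
CONDITIONING = {
    Setting.APRIORI_UBM: (),
    Setting.APRIORI_MST: (),
    Setting.WITH_FIRST: (1,),
    Setting.WITH_SECOND: (2,),
    Setting.WITH_BOTH: (1, 2),
}


@dataclass(frozen=True)
class ForecastTask:
    episode_id: str
    observations: tuple[ConcentrationObservation, ...]  # first three, time-sorted
    covariates: CovariateVector  # frozen at the 2nd measurement
    doses: tuple[DoseEvent, ...]  # administered before the forecast timepoint

    @property
    def forecast_time(self) -> float:
        return self.observations[2].time

    @property
    def measured_third(self) -> float:
        return self.observations[2].value


@dataclass(frozen=True)
class ForecastCell:
    tool: str
    setting: Setting
    mean_ppe: float
    mean_pape: float
    n: int
    n_failed: int


def select_assessment_episodes(
    episodes: Sequence[TreatmentEpisode],
    required_covariates: Sequence[str] = (),
    egfr_version: str = "2009",
) -> tuple[list[ForecastTask], dict[str, str]]:
    """Build one forecast task per qualifying episode.

    Returns the tasks and a map episode_id → exclusion reason for the rest.
    """
    tasks: list[ForecastTask] = []
    excluded: dict[str, str] = {}
    for ep in episodes:
        if not ep.in_icu(0.0):
            excluded[ep.episode_id] = "did not start in ICU"
            continue
        if len(ep.observations) < 3:
            excluded[ep.episode_id] = "fewer than 3 concentrations"
            continue
        first_three = tuple(ep.observations[:3])
        if not first_three[2].is_trough:
            excluded[ep.episode_id] = "3rd concentration is not a trough"
            continue
        covariates = freeze_covariates(ep, first_three[1].time, egfr_version=egfr_version)
        if covariates is None:
            excluded[ep.episode_id] = "missing covariates"
            continue
        missing = [c for c in required_covariates if c not in covariates]
        if missing:
            excluded[ep.episode_id] = f"missing covariates: {missing}"
            continue
        doses = tuple(d for d in ep.doses if d.time < first_three[2].time)
        if not doses:
            excluded[ep.episode_id] = "no dose before the 3rd concentration"
            continue
        tasks.append(
            ForecastTask(
                episode_id=ep.episode_id,
                observations=first_three,
                covariates=covariates,
                doses=doses,
            )
        )
    return tasks, excluded


def _resolve_model(
    task: ForecastTask,
    tool: PKModelSpec | DecisionTree,
    registry: Sequence[PKModelSpec],
) -> PKModelSpec:
    if isinstance(tool, PKModelSpec):
        return tool
    name = apply_mst(tool, task.covariates)
    for spec in registry:
        if spec.name == name:
            return spec
    raise PredictionError(f"MST selected model {name!r} absent from the registry")


def forecast_third(
    task: ForecastTask,
    tool: PKModelSpec | DecisionTree,
    registry: Sequence[PKModelSpec] = (),
    setting: Setting = Setting.APRIORI_UBM,
    seed: int = 0,
) -> float:
    """Predict the third concentration (mg/L) under one information setting."""
    spec = _resolve_model(task, tool, registry)
    conditioning = [task.observations[i - 1] for i in CONDITIONING[setting]]
    if conditioning:
        etas = map_estimate(spec, task.covariates, task.doses, conditioning, seed=seed)
    else:
        etas = IndividualParameters()
    result = predict_concentration(
        spec, task.covariates, task.doses, [task.forecast_time], etas
    )
    return float(result.predicted[0])


def evaluate_forecasting(
    tasks: Sequence[ForecastTask],
    tools: dict[str, PKModelSpec | DecisionTree],
    registry: Sequence[PKModelSpec] = (),
    settings: Sequence[Setting] = tuple(Setting),
    seed: int = 0,
) -> tuple[list[ForecastCell], pd.DataFrame]:
    """Mean PPE / mean PAPE per tool × setting over all tasks.

    MAP failures are recorded as missing forecasts and excluded from the
    means with their count.  Returns the report cells and a per-task log.
    """
    if not tasks:
        raise ValueError("at least one forecast task is required")
    cells: list[ForecastCell] = []
    log_rows: list[dict] = []
    for tool_name, tool in tools.items():
        for setting in settings:
            # a priori with a fixed model is UBM-style; with a tree, MST-style
            ppes: list[float] = []
            n_failed = 0
            for task in tasks:
                try:
                    predicted = forecast_third(task, tool, registry, setting, seed=seed)
                except (EstimationError, PredictionError):
                    n_failed += 1
                    continue
                err = ppe(task.measured_third, predicted)
                ppes.append(err)
                log_rows.append(
                    {
                        "episode_id": task.episode_id,
                        "tool": tool_name,
                        "setting": setting.value,
                        "measured": task.measured_third,
                        "predicted": predicted,
                        "ppe_pct": err,
                        "pape_pct": abs(err),
                    }
                )
            if ppes:
                cells.append(
                    ForecastCell(
                        tool=tool_name,
                        setting=setting,
                        mean_ppe=float(np.mean(ppes)),
                        mean_pape=float(np.mean(np.abs(ppes))),
                        n=len(ppes),
                        n_failed=n_failed,
                    )
                )
    return cells, pd.DataFrame(log_rows)


def report_frame(cells: Sequence[ForecastCell]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tool": c.tool,
                "setting": c.setting.value,
                "n": c.n,
                "n_failed": c.n_failed,
                "mean_ppe_pct": c.mean_ppe,
                "mean_pape_pct": c.mean_pape,
            }
            for c in cells
        ]
    )
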