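"""Prediction-error metrics and universally-best-model selection.

Bias and precision of a model on a set of evaluation timeframes are
summarised by the percentage prediction error

    PPE  = (measured − predicted) / measured × 100 %

(positive = underprediction) and its absolute value, PAPE.  The universally
best-performing model (UBM) of a registry is the one minimizing the
selection score |mean PPE| + mean PAPE, which penalises bias and imprecision
on the same scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .covariates import Timeframe
from .pk import PKModelSpec, PredictionError, population_predict


def ppe(measured: float, predicted: float) -> float:
    """Percentage prediction error, %; positive when the model underpredicts."""
    if not measured > 0:
        raise ValueError(f"measured concentration must be positive, got {measured}")
    return (measured - predicted) / measured * 100.0


def pape(measured: float, predicted: float) -> float:
    """Percentage absolute prediction error, % (|PPE|)."""
    return abs(ppe(measured, predicted))


@dataclass(frozen=True)
class ErrorRecord:
    timeframe_index: int
    model_name: str
    ppe_values: tuple[float, ...]  # per-observation, %

    @property
    def pape_values(self) -> tuple[float, ...]:
        return tuple(abs(v) for v in self.ppe_values)


@dataclass(frozen=True)
class EvaluationReport:
    model_name: str
    mean_ppe: float  # %
    mean_pape: float  # %
    n_observations: int
    n_timeframes: int

    @property
    def selection_score(self) -> float:
        """|mean PPE| + mean PAPE, %."""
        return selection_score(self.mean_ppe, self.mean_pape)


def selection_score(mean_ppe: float, mean_pape: float) -> float:
    """The UBM criterion: sum of |mean PPE| and mean PAPE (both %)."""
    return abs(mean_ppe) + mean_pape


def aggregate_errors(
    records: Sequence[ErrorRecord], per_timeframe: bool = False
) -> EvaluationReport:
    """Mean PPE / mean PAPE over error records of a single model.

    Default pools all observation-level errors; ``per_timeframe=True``
    averages within each timeframe first, then across timeframes.
    """
    if not records:
        raise ValueError("cannot aggregate an empty list of error records")
    names = {r.model_name for r in records}
    if len(names) > 1:
        raise ValueError(f"records mix models: {sorted(names)}")
    if per_timeframe:
        ppe_units = [float(np.mean(r.ppe_values)) for r in records]
        pape_units = [float(np.mean(r.pape_values)) for r in records]
    else:
        ppe_units = [v for r in records for v in r.ppe_values]
        pape_units = [v for r in records for v in r.pape_values]
    return EvaluationReport(
        model_name=names.pop(),
        mean_ppe=float(np.mean(ppe_units)),
        mean_pape=float(np.mean(pape_units)),
        n_observations=sum(len(r.ppe_values) for r in records),
        n_timeframes=len(records),
    )


class ErrorTable:
    """Observation-level PPE of every registry model on every timeframe.

    Population predictions are computed once; selection, labelling and
    cross-validated fitness then reduce to array lookups.  Entry
    ``ppe[model][timeframe]`` is the per-observation PPE array (%), or None
    when the model is not evaluable on that timeframe (missing covariates).
    """

    def __init__(self, registry: Sequence[PKModelSpec], timeframes: Sequence[Timeframe]):
        self.registry = list(registry)
        self.timeframes = list(timeframes)
        self.model_names = [m.name for m in self.registry]
        self._ppe: list[list[np.ndarray | None]] = []
        self.n_skipped: dict[str, int] = {}
        for spec in self.registry:
            row: list[np.ndarray | None] = []
            skipped = 0
            for tf in self.timeframes:
                try:
                    pred = population_predict(
                        spec,
                        tf.frozen_covariates,
                        tf.doses,
                        [o.time for o in tf.target_observations],
                    ).predicted
                except PredictionError:
                    row.append(None)
                    skipped += 1
                    continue
                measured = np.array([o.value for o in tf.target_observations])
                row.append((measured - pred) / measured * 100.0)
            self._ppe.append(row)
            self.n_skipped[spec.name] = skipped

    def ppe_values(self, model_index: int, timeframe_index: int) -> np.ndarray | None:
        return self._ppe[model_index][timeframe_index]

    def timeframe_mean_pape(self, model_index: int, timeframe_index: int) -> float:
        values = self._ppe[model_index][timeframe_index]
        if values is None:
            return float("inf")
        return float(np.mean(np.abs(values)))

    def records(self, model_index: int, timeframe_indices: Sequence[int] | None = None) -> list[ErrorRecord]:
        indices = range(len(self.timeframes)) if timeframe_indices is None else timeframe_indices
        out = []
        for i in indices:
            values = self._ppe[model_index][i]
            if values is not None:
                out.append(
                    ErrorRecord(i, self.model_names[model_index], tuple(float(v) for v in values))
                )
        return out

    def report(self, model_index: int, per_timeframe: bool = False) -> EvaluationReport:
        recs = self.records(model_index)
        if not recs:
            raise ValueError(f"model {self.model_names[model_index]!r} evaluable on no timeframe")
        return aggregate_errors(recs, per_timeframe=per_timeframe)

    def reports(self, per_timeframe: bool = False) -> list[EvaluationReport]:
        return [self.report(i, per_timeframe=per_timeframe) for i in range(len(self.registry))]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, rep in enumerate(self.reports()):
            rows.append(
                {
                    "model": rep.model_name,
                    "n_obs": rep.n_observations,
                    "n_timeframes": rep.n_timeframes,
                    "n_skipped": self.n_skipped[rep.model_name],
                    "mean_ppe_pct": rep.mean_ppe,
                    "mean_pape_pct": rep.mean_pape,
                    "selection_score_pct": rep.selection_score,
                }
            )
        return pd.DataFrame(rows)


class UniversalBestModel(BaseEstimator):
    """Selects the registry model with the lowest |mean PPE| + mean PAPE.

    Parameters
    ----------
    registry : list of PKModelSpec
        Candidate one-compartment population models; ties in the selection
        score break toward the lower registry index.
    per_timeframe : bool, default False
        Average errors within each timeframe before pooling.

    Attributes
    ----------
    best_model_ : PKModelSpec
    best_model_name_ : str
    report_ : EvaluationReport for the selected model
    reports_ : list of EvaluationReport, registry order
    """

    def __init__(self, registry: Sequence[PKModelSpec] = (), per_timeframe: bool = False):
        self.registry = registry
        self.per_timeframe = per_timeframe

    def fit(self, X: Sequence[Timeframe], y: None = None) -> "UniversalBestModel":
        if not self.registry:
            raise ValueError("registry must contain at least one model")
        if not X:
            raise ValueError("at least one timeframe is required")
        table = X if isinstance(X, ErrorTable) else ErrorTable(self.registry, X)
        reports = []
        for i in range(len(table.registry)):
            try:
                reports.append(table.report(i, per_timeframe=self.per_timeframe))
            except ValueError:
                reports.append(None)
        if all(r is None for r in reports):
            raise ValueError("no model is evaluable on any timeframe")
        best_i = min(
            (i for i, r in enumerate(reports) if r is not None),
            key=lambda i: reports[i].selection_score,
        )
        self.error_table_ = table
        self.reports_ = reports
        self.best_index_ = best_i
        self.best_model_ = table.registry[best_i]
        self.best_model_name_ = table.model_names[best_i]
        self.report_ = reports[best_i]
        return self

    def predict(self, X: Sequence) -> list[str]:
        """The UBM is unconditional: the same model for every input."""
        return [self.best_model_name_ for _ in X]


def select_universal_best(
    registry: Sequence[PKModelSpec],
    timeframes: Sequence[Timeframe] | ErrorTable,
    per_timeframe: bool = False,
) -> tuple[str, EvaluationReport]:
    """Functional wrapper over :class:`UniversalBestModel`."""
    ubm = UniversalBestModel(registry=list(registry), per_timeframe=per_timeframe).fit(timeframes)
    return ubm.best_model_name_, ubm.report_
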