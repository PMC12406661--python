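"""Cohort tables, treatment episodes and trough labelling.

A *treatment episode* is one patient's contiguous intravenous vancomycin
course: dose events, measured plasma concentrations, time-stamped covariate
series and ICU / renal-replacement-therapy (RRT) intervals.  Courses of the
same patient separated by a gap of at least seven days between consecutive
doses are split into separate episodes.

All times inside an episode are hours since the episode's first dose.
Input CSVs may carry either ISO-8601 timestamps or plain hour floats; both
are converted on read.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Gap between consecutive doses (hours) that starts a new episode: 7 days.
EPISODE_GAP_H = 168.0

#: Trough window relative to the scheduled start of the next infusion:
#: from 2.5 h before to 0.5 h after.
TROUGH_BEFORE_H = 2.5
TROUGH_AFTER_H = 0.5


class CohortFormatError(ValueError):
    """A cohort CSV is missing a mandatory column."""


class CohortValidationError(ValueError):
    """A cohort row violates a domain invariant (e.g. non-positive dose)."""


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    sex: str  # "male" | "female"
    age: float  # years, adult cohort (>= 18)
    height: float  # cm

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise CohortValidationError(f"sex must be male/female, got {self.sex!r}")
        if not self.age >= 18:
            raise CohortValidationError(f"adult cohort requires age >= 18, got {self.age}")
        if not self.height > 0:
            raise CohortValidationError(f"height must be positive, got {self.height}")


@dataclass(frozen=True)
class DoseEvent:
    time: float  # h since episode start
    amount: float  # mg
    infusion_duration: float  # h
    scheduled_time: float | None = None  # h; falls back to actual time

    def __post_init__(self) -> None:
        if not self.amount > 0:
            raise CohortValidationError(f"dose amount must be positive, got {self.amount}")
        if not self.infusion_duration > 0:
            raise CohortValidationError(
                f"infusion duration must be positive, got {self.infusion_duration}"
            )

    @property
    def anchor_time(self) -> float:
        """Schedule anchor for trough labelling (scheduled time, else actual)."""
        return self.time if self.scheduled_time is None else self.scheduled_time


@dataclass(frozen=True)
class ConcentrationObservation:
    time: float  # h since episode start
    value: float  # mg/L
    is_trough: bool = False

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise CohortValidationError(
                f"concentration must be positive, got {self.value}"
            )


@dataclass
class CovariateSeries:
    """A named, time-sorted covariate series; labs get the ±48 h imputation rule."""

    name: str
    points: list[tuple[float, float]]  # (hours, value), time-sorted
    is_lab: bool = False

    def __post_init__(self) -> None:
        self.points = sorted(self.points, key=lambda p: p[0])

    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.points], dtype=float)

    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.points], dtype=float)


@dataclass
class TreatmentEpisode:
    patient: PatientRecord
    episode_id: str
    doses: list[DoseEvent]
    observations: list[ConcentrationObservation]
    covariates: list[CovariateSeries] = field(default_factory=list)
    icu_intervals: list[tuple[float, float]] = field(default_factory=list)
    rrt_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.doses:
            raise CohortValidationError(f"episode {self.episode_id} has no doses")
        self.doses = sorted(self.doses, key=lambda d: d.time)
        self.observations = sorted(self.observations, key=lambda o: o.time)
        for name, ivals in (("icu", self.icu_intervals), ("rrt", self.rrt_intervals)):
            for start, end in ivals:
                if not start < end:
                    raise CohortValidationError(
                        f"episode {self.episode_id}: {name} interval start {start} >= end {end}"
                    )

    def covariate(self, name: str) -> CovariateSeries | None:
        for series in self.covariates:
            if series.name == name:
                return series
        return None

    def in_rrt(self, t: float) -> bool:
        return any(start <= t < end for start, end in self.rrt_intervals)

    def in_icu(self, t: float) -> bool:
        # An episode read without any ICU flag is treated as fully in the ICU
        # (the cohorts this tool targets are ICU cohorts by inclusion criterion).
        if not self.icu_intervals:
            return True
        return any(start <= t < end for start, end in self.icu_intervals)


# ---------------------------------------------------------------------------
# episode splitting


def split_episodes(dose_times: Sequence[float]) -> list[tuple[int, int]]:
    """Partition sorted dose times into episodes at gaps of >= 7 days.

    Returns half-open index ranges ``(start, end)`` into ``dose_times``;
    a gap of exactly 168 h starts a new episode.
    """
    times = list(dose_times)
    if times != sorted(times):
        raise ValueError("dose_times must be sorted ascending")
    if not times:
        return []
    bounds = [0]
    for i in range(1, len(times)):
        if times[i] - times[i - 1] >= EPISODE_GAP_H:
            bounds.append(i)
    bounds.append(len(times))
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


# ---------------------------------------------------------------------------
# trough labelling


def label_troughs(episode: TreatmentEpisode) -> TreatmentEpisode:
    """Flag observations drawn in the trough window of any scheduled dose.

    An observation is a trough iff its time lies within
    ``[s - 2.5 h, s + 0.5 h]`` for the scheduled start ``s`` of some dose.
    Observations later than 0.5 h after the final scheduled dose are never
    troughs (there is no next dose to be a trough for).
    """
    anchors = [d.anchor_time for d in episode.doses]
    labelled = [
        dataclasses.replace(
            obs,
            is_trough=any(
                s - TROUGH_BEFORE_H <= obs.time <= s + TROUGH_AFTER_H for s in anchors
            ),
        )
        for obs in episode.observations
    ]
    return dataclasses.replace(episode, observations=labelled)


# ---------------------------------------------------------------------------
# CSV I/O

_PATIENT_COLS = ["patient_id", "sex", "age_years", "height_cm"]
_DOSE_COLS = ["patient_id", "time", "amount_mg", "infusion_duration_h"]
_CONC_COLS = ["patient_id", "time", "value_mg_per_L"]
_COV_COLS = ["patient_id", "time", "name", "value"]

#: Covariate names treated as laboratory values (±48 h imputation window).
LAB_COVARIATES = {"creatinine_umol_L"}

#: Flag series converted to intervals rather than kept as covariates.
_FLAG_COVARIATES = {"rrt_active", "icu_active"}


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing mandatory column(s) {missing}")


def _parse_times(raw: pd.Series) -> np.ndarray:
    """Times as absolute hours; accepts plain floats or ISO-8601 timestamps."""
    numeric = pd.to_numeric(raw, errors="coerce")
    if numeric.notna().all():
        return numeric.to_numpy(dtype=float)
    stamps = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    if stamps.isna().any():
        bad = raw[stamps.isna() & numeric.isna()]
        raise CohortFormatError(f"unparseable time value(s): {bad.head().tolist()}")
    epoch = pd.Timestamp("1970-01-01")
    return ((stamps - epoch) / pd.Timedelta(hours=1)).to_numpy(dtype=float)


def _flags_to_intervals(times: np.ndarray, values: np.ndarray, end: float) -> list[tuple[float, float]]:
    """Convert a 0/1 step series into half-open active intervals up to *end*."""
    intervals: list[tuple[float, float]] = []
    start: float | None = None
    order = np.argsort(times)
    for t, v in zip(times[order], values[order]):
        active = v >= 0.5
        if active and start is None:
            start = float(t)
        elif not active and start is not None:
            if t > start:
                intervals.append((start, float(t)))
            start = None
    if start is not None and end > start:
        intervals.append((start, end))
    return intervals


def read_cohort(
    patients_path: str | Path,
    doses_path: str | Path,
    concentrations_path: str | Path,
    covariates_path: str | Path | None = None,
) -> list[TreatmentEpisode]:
    """Assemble treatment episodes from the four cohort CSVs.

    Episodes are split at inter-dose gaps of >= 7 days; all times are
    re-expressed as hours since each episode's first dose; troughs are
    labelled from the dose schedule.
    """
    patients = pd.read_csv(patients_path, dtype={"patient_id": str}, float_precision="round_trip")
    _require_columns(patients, _PATIENT_COLS, str(patients_path))
    doses = pd.read_csv(doses_path, dtype={"patient_id": str}, float_precision="round_trip")
    _require_columns(doses, _DOSE_COLS, str(doses_path))
    concs = pd.read_csv(concentrations_path, dtype={"patient_id": str}, float_precision="round_trip")
    _require_columns(concs, _CONC_COLS, str(concentrations_path))
    if covariates_path is not None:
        covs = pd.read_csv(covariates_path, dtype={"patient_id": str}, float_precision="round_trip")
        _require_columns(covs, _COV_COLS, str(covariates_path))
    else:
        covs = pd.DataFrame(columns=_COV_COLS)

    for idx, amount in doses["amount_mg"].items():
        if not amount > 0:
            raise CohortValidationError(f"doses row {idx}: non-positive amount {amount}")
    for idx, value in concs["value_mg_per_L"].items():
        if not value > 0:
            raise CohortValidationError(
                f"concentrations row {idx}: non-positive concentration {value}"
            )

    doses = doses.assign(_t=_parse_times(doses["time"]))
    if "scheduled_time" in doses.columns and doses["scheduled_time"].notna().any():
        doses = doses.assign(_sched=_parse_times(doses["scheduled_time"].fillna(doses["time"])))
    else:
        doses = doses.assign(_sched=doses["_t"])
    concs = concs.assign(_t=_parse_times(concs["time"])) if len(concs) else concs.assign(_t=[])
    covs = covs.assign(_t=_parse_times(covs["time"])) if len(covs) else covs.assign(_t=[])

    episodes: list[TreatmentEpisode] = []
    for _, prow in patients.iterrows():
        pid = prow["patient_id"]
        patient = PatientRecord(
            patient_id=pid,
            sex=str(prow["sex"]).lower(),
            age=float(prow["age_years"]),
            height=float(prow["height_cm"]),
        )
        pdoses = doses[doses["patient_id"] == pid].sort_values("_t")
        if pdoses.empty:
            continue
        pconcs = concs[concs["patient_id"] == pid]
        pcovs = covs[covs["patient_id"] == pid]
        dose_times = pdoses["_t"].to_numpy()
        spans = split_episodes(list(dose_times))
        for ep_num, (i0, i1) in enumerate(spans, start=1):
            origin = dose_times[i0]
            upper = dose_times[i1] if i1 < len(dose_times) else np.inf
            chunk = pdoses.iloc[i0:i1]
            ep_doses = [
                DoseEvent(
                    time=float(r["_t"] - origin),
                    amount=float(r["amount_mg"]),
                    infusion_duration=float(r["infusion_duration_h"]),
                    scheduled_time=float(r["_sched"] - origin),
                )
                for _, r in chunk.iterrows()
            ]
            in_span = (pconcs["_t"] >= origin) & (pconcs["_t"] < upper)
            ep_obs = [
                ConcentrationObservation(time=float(r["_t"] - origin), value=float(r["value_mg_per_L"]))
                for _, r in pconcs[in_span].iterrows()
            ]
            cov_in = pcovs[(pcovs["_t"] >= origin - EPISODE_GAP_H) & (pcovs["_t"] < upper)]
            series: list[CovariateSeries] = []
            icu_intervals: list[tuple[float, float]] = []
            rrt_intervals: list[tuple[float, float]] = []
            span_end = float(ep_doses[-1].time + 24.0)
            for name, group in cov_in.groupby("name"):
                rel_t = group["_t"].to_numpy(dtype=float) - origin
                vals = pd.to_numeric(group["value"]).to_numpy(dtype=float)
                if name in _FLAG_COVARIATES:
                    ivals = _flags_to_intervals(rel_t, vals, span_end)
                    if name == "icu_active":
                        icu_intervals = ivals
                    else:
                        rrt_intervals = ivals
                else:
                    dedup: dict[float, float] = {}
                    for t, v in zip(rel_t, vals):
                        dedup.setdefault(float(t), float(v))
                    series.append(
                        CovariateSeries(
                            name=str(name),
                            points=sorted(dedup.items()),
                            is_lab=name in LAB_COVARIATES,
                        )
                    )
            episode = TreatmentEpisode(
                patient=patient,
                episode_id=f"{pid}-e{ep_num}",
                doses=ep_doses,
                observations=ep_obs,
                covariates=series,
                icu_intervals=icu_intervals,
                rrt_intervals=rrt_intervals,
            )
            episodes.append(label_troughs(episode))
    return episodes


def write_cohort(episodes: Sequence[TreatmentEpisode], out_dir: str | Path) -> dict[str, Path]:
    """Write episodes back to the four cohort CSVs (times in hours).

    Within a patient, later episodes are offset by multiples of 10,000 h so
    the ≥7-day splitter reconstructs the same episodes on re-read; a
    patient's first episode keeps its times verbatim (bit-exact round trip).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prows, drows, crows, vrows = [], [], [], []
    seen: set[str] = set()
    episode_count: dict[str, int] = {}
    for ep in episodes:
        k = episode_count.get(ep.patient.patient_id, 0)
        episode_count[ep.patient.patient_id] = k + 1
        offset = 10_000.0 * k
        p = ep.patient
        if p.patient_id not in seen:
            seen.add(p.patient_id)
            prows.append(
                {"patient_id": p.patient_id, "sex": p.sex, "age_years": p.age, "height_cm": p.height}
            )
        for d in ep.doses:
            drows.append(
                {
                    "patient_id": p.patient_id,
                    "time": d.time + offset,
                    "amount_mg": d.amount,
                    "infusion_duration_h": d.infusion_duration,
                    "scheduled_time": d.anchor_time + offset,
                }
            )
        for o in ep.observations:
            crows.append(
                {"patient_id": p.patient_id, "time": o.time + offset, "value_mg_per_L": o.value}
            )
        for s in ep.covariates:
            for t, v in s.points:
                vrows.append(
                    {"patient_id": p.patient_id, "time": t + offset, "name": s.name, "value": v}
                )
        for name, ivals in (("icu_active", ep.icu_intervals), ("rrt_active", ep.rrt_intervals)):
            for start, end in ivals:
                vrows.append({"patient_id": p.patient_id, "time": start + offset, "name": name, "value": 1})
                vrows.append({"patient_id": p.patient_id, "time": end + offset, "name": name, "value": 0})
    paths = {
        "patients": out / "patients.csv",
        "doses": out / "doses.csv",
        "concentrations": out / "concentrations.csv",
        "covariates": out / "covariates.csv",
    }
    pd.DataFrame(prows, columns=_PATIENT_COLS).to_csv(paths["patients"], index=False)
    pd.DataFrame(drows, columns=_DOSE_COLS + ["scheduled_time"]).to_csv(paths["doses"], index=False)
    pd.DataFrame(crows, columns=_CONC_COLS).to_csv(paths["concentrations"], index=False)
    pd.DataFrame(vrows, columns=_COV_COLS).to_csv(paths["covariates"], index=False)
    return paths


def read_cohort_dir(cohort_dir: str | Path) -> list[TreatmentEpisode]:
    """Read a directory holding patients/doses/concentrations/covariates CSVs."""
    d = Path(cohort_dir)
    cov = d / "covariates.csv"
    return read_cohort(
        d / "patients.csv",
        d / "doses.csv",
        d / "concentrations.csv",
        cov if cov.exists() else None,
    )
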