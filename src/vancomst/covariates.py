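"""Derived covariates, imputation and evaluation timeframes.

Derived covariates follow the clinical formulas used for vancomycin dosing:
ideal body weight (Devine), Cockcroft-Gault creatinine clearance computed on
ideal body weight with creatinine in µmol/L, and the CKD-EPI creatinine
eGFR (2009 equation, race coefficient omitted; the 2021 race-free refit is
selectable).

Evaluation *timeframes* are windows of at most 72 h that start either at
treatment initiation or at a concentration measurement and contain the next
two measured concentrations.  Covariates are frozen at the window start —
the information that would be available for real-time forecasting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .cohort import (
    ConcentrationObservation,
    CovariateSeries,
    DoseEvent,
    TreatmentEpisode,
)

#: Maximum timeframe length (h).
MAX_TIMEFRAME_H = 72.0

#: Lab imputation window (h).
LAB_WINDOW_H = 48.0

CovariateVector = dict[str, float]


def ideal_body_weight(sex: str, height_cm: float) -> float:
    """Devine ideal body weight, kg: 45 (F) / 50 (M) + 1 kg per cm above 150 cm."""
    if not height_cm > 0:
        raise ValueError(f"height must be positive, got {height_cm}")
    base = 45.0 if sex == "female" else 50.0
    return base + max(0.0, height_cm - 150.0)


def cockcroft_gault_crcl(
    age_years: float, sex: str, height_cm: float, creatinine_umol_L: float
) -> float:
    """Cockcroft-Gault creatinine clearance (mL/min) on ideal body weight.

    ((140 − age) × IBW / creatinine[µmol/L]) × 0.85 if female; clamped at 0.
    """
    if not creatinine_umol_L > 0:
        raise ValueError(f"creatinine must be positive, got {creatinine_umol_L}")
    ibw = ideal_body_weight(sex, height_cm)
    crcl = (140.0 - age_years) * ibw / creatinine_umol_L
    if sex == "female":
        crcl *= 0.85
    return max(0.0, crcl)


def ckd_epi_egfr(
    age_years: float, sex: str, creatinine_umol_L: float, version: str = "2009"
) -> float:
    """CKD-EPI creatinine eGFR (mL/min/1.73 m²).

    ``version="2009"`` (default): the 2009 equation with the race coefficient
    omitted.  ``version="2021"``: the race-free refit.  Creatinine is
    converted µmol/L → mg/dL by dividing by 88.4.
    """
    if not creatinine_umol_L > 0:
        raise ValueError(f"creatinine must be positive, got {creatinine_umol_L}")
    scr = creatinine_umol_L / 88.4  # mg/dL
    female = sex == "female"
    if version == "2009":
        kappa = 0.7 if female else 0.9
        alpha = -0.329 if female else -0.411
        coef, age_base = 141.0, 0.993
    elif version == "2021":
        kappa = 0.7 if female else 0.9
        alpha = -0.241 if female else -0.302
        coef, age_base = 142.0, 0.9938
    else:
        raise ValueError(f"unknown CKD-EPI version {version!r}")
    ratio = scr / kappa
    egfr = (
        coef
        * min(ratio, 1.0) ** alpha
        * max(ratio, 1.0) ** -1.209
        * age_base**age_years
    )
    if female:
        egfr *= 1.018 if version == "2009" else 1.012
    return egfr


def body_mass_index(weight_kg: float, height_cm: float) -> float:
    if not (weight_kg > 0 and height_cm > 0):
        raise ValueError("weight and height must be positive")
    return weight_kg / (height_cm / 100.0) ** 2


def treatment_day(t_hours: float) -> int:
    """1-based treatment day relative to the episode's first dose."""
    return int(math.floor(t_hours / 24.0)) + 1


# ---------------------------------------------------------------------------
# imputation


def impute_covariate(series: CovariateSeries, query_time: float) -> float | None:
    """Value of a covariate at *query_time* under the study's imputation rules.

    Labs: the nearest point within ±48 h (tie: the earlier point, i.e. the
    value already available in real time).  Non-labs: an exact same-day value,
    else the first available among the days −1, +1, −2, +2 relative to the
    query day.  Returns ``None`` when nothing qualifies.
    """
    if not series.points:
        return None
    if series.is_lab:
        best: tuple[float, float] | None = None  # (|dt|, value); earlier wins ties
        for t, v in series.points:
            dt = abs(t - query_time)
            if dt > LAB_WINDOW_H:
                continue
            if best is None or dt < best[0] - 1e-12:
                best = (dt, v)
            # equal distance: points iterate time-sorted, so the first
            # (earlier) point is kept
        return None if best is None else best[1]
    qday = math.floor(query_time / 24.0)
    for offset in (0, -1, +1, -2, +2):
        day = qday + offset
        candidates = [(abs(t - query_time), v) for t, v in series.points
                      if math.floor(t / 24.0) == day]
        if candidates:
            return min(candidates, key=lambda c: c[0])[1]
    return None


def _closest_value(series: CovariateSeries, query_time: float) -> float | None:
    if not series.points:
        return None
    return min(series.points, key=lambda p: abs(p[0] - query_time))[1]


# ---------------------------------------------------------------------------
# frozen covariate vectors


def freeze_covariates(
    episode: TreatmentEpisode, t: float, egfr_version: str = "2009"
) -> CovariateVector | None:
    """Covariate vector at time *t*, as available for real-time forecasting.

    Missing weight/creatinine at ``t`` is imputed by the study rules, then by
    the closest value anywhere in the episode; returns ``None`` only when the
    episode carries no value at all for a required covariate.  ``sex`` is
    encoded 1.0 = male, 0.0 = female.
    """
    p = episode.patient
    vec: CovariateVector = {
        "age": float(p.age),
        "sex": 1.0 if p.sex == "male" else 0.0,
        "height": float(p.height),
        "treatment_day": float(treatment_day(t)),
        "rrt_active": 1.0 if episode.in_rrt(t) else 0.0,
    }
    for name, key in (("weight_kg", "weight"), ("creatinine_umol_L", "creatinine")):
        series = episode.covariate(name)
        if series is None:
            return None
        value = impute_covariate(series, t)
        if value is None:
            value = _closest_value(series, t)
        if value is None:
            return None
        vec[key] = float(value)
    vec["bmi"] = body_mass_index(vec["weight"], p.height)
    vec["crcl_cg"] = cockcroft_gault_crcl(p.age, p.sex, p.height, vec["creatinine"])
    vec["egfr_ckd_epi"] = ckd_epi_egfr(p.age, p.sex, vec["creatinine"], version=egfr_version)
    return vec


# ---------------------------------------------------------------------------
# timeframes


@dataclass
class Timeframe:
    """An evaluation window (≤ 72 h) with frozen covariates.

    Self-contained for prediction: carries the episode's full dose history so
    concentrations at the target times can be computed without the episode.
    """

    episode_id: str
    start: float
    end: float
    subset: str  # "RRT" | "non-RRT"
    frozen_covariates: CovariateVector
    target_observations: list[ConcentrationObservation]
    doses: list[DoseEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end - self.start > MAX_TIMEFRAME_H + 1e-9:
            raise ValueError(f"timeframe longer than {MAX_TIMEFRAME_H} h")
        if len(self.target_observations) < 2:
            raise ValueError("timeframe must contain at least two target observations")
        for obs in self.target_observations:
            if not (self.start < obs.time <= self.end + 1e-9):
                raise ValueError("target observation outside (start, end]")


def _constant_rrt_spans(
    episode: TreatmentEpisode, lo: float, hi: float
) -> list[tuple[float, float, bool]]:
    """Split [lo, hi) into maximal spans of constant RRT status."""
    cuts = {lo, hi}
    for s, e in episode.rrt_intervals:
        for c in (s, e):
            if lo < c < hi:
                cuts.add(c)
    edges = sorted(cuts)
    return [
        (a, b, episode.in_rrt(a)) for a, b in zip(edges[:-1], edges[1:]) if b > a
    ]


def build_timeframes(
    episode: TreatmentEpisode, egfr_version: str = "2009"
) -> list[Timeframe]:
    """Construct all valid evaluation timeframes of an episode.

    Within each ICU period, split by RRT status; candidate starts are the
    treatment initiation and every concentration time; each candidate extends
    to the next two concentrations in the same span; spans longer than 72 h
    are discarded, as are candidates whose covariates cannot be frozen.
    """
    icu = episode.icu_intervals or [(0.0, max(d.time for d in episode.doses) + 24.0)]
    frames: list[Timeframe] = []
    for icu_start, icu_end in icu:
        for lo, hi, is_rrt in _constant_rrt_spans(episode, icu_start, icu_end):
            obs = [o for o in episode.observations if lo <= o.time < hi]
            starts: list[float] = []
            if lo <= 0.0 < hi:
                starts.append(0.0)
            starts.extend(o.time for o in obs)
            for start in starts:
                targets = [o for o in obs if o.time > start][:2]
                if len(targets) < 2:
                    continue
                end = targets[-1].time
                if end - start > MAX_TIMEFRAME_H:
                    continue
                frozen = freeze_covariates(episode, start, egfr_version=egfr_version)
                if frozen is None:
                    continue
                frames.append(
                    Timeframe(
                        episode_id=episode.episode_id,
                        start=start,
                        end=end,
                        subset="RRT" if is_rrt else "non-RRT",
                        frozen_covariates=frozen,
                        target_observations=targets,
                        doses=list(episode.doses),
                    )
                )
    return frames


def build_cohort_timeframes(
    episodes: Sequence[TreatmentEpisode], egfr_version: str = "2009"
) -> list[Timeframe]:
    frames: list[Timeframe] = []
    for ep in episodes:
        frames.extend(build_timeframes(ep, egfr_version=egfr_version))
    return frames


def timeframes_report(frames: Sequence[Timeframe]) -> pd.DataFrame:
    """Derived-covariate report: one row per timeframe, frozen values as columns."""
    rows = []
    for tf in frames:
        row = {
            "episode_id": tf.episode_id,
            "timeframe_start": tf.start,
            "timeframe_end": tf.end,
            "subset": tf.subset,
        }
        row.update(tf.frozen_covariates)
        rows.append(row)
    return pd.DataFrame(rows)
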