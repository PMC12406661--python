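"""Synthetic ICU vancomycin cohorts with known generating pharmacokinetics.

The generator emulates the statistical structure the selection pipeline
assumes: adult ICU patients (median age 63, ~76% male), guideline dosing
(1,000 mg q12h when Cockcroft-Gault CrCl > 50 mL/min, otherwise a single
1,000 mg load followed by trough-guided redosing), trough-dominant sampling
drawn just before a daily dose inside the trough window, a creatinine
trajectory evolving as a bounded geometric random walk, RRT in ~30% of
episodes, and treatment durations with median 8 days.

Each patient's concentrations are generated from a known one-compartment
model chosen by which eGFR *region* the patient falls in, with log-normal
individual parameters and proportional residual noise — so subgroup
recovery is testable exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .cohort import (
    ConcentrationObservation,
    CovariateSeries,
    DoseEvent,
    PatientRecord,
    TreatmentEpisode,
    label_troughs,
)
from .covariates import (
    CovariateVector,
    body_mass_index,
    ckd_epi_egfr,
    cockcroft_gault_crcl,
)
from .pk import ErrorModel, IndividualParameters, PKModelSpec, make_model
from .pk import _concentration_profile


def default_generating_model() -> PKModelSpec:
    """A realistic renally-cleared vancomycin model for adults.

    CL = 0.3 + 0.044·CrCl (L/h), V = 0.7·weight (L); at the cohort medians
    (CrCl ≈ 70 mL/min, weight ≈ 82 kg) the steady-state trough under
    1,000 mg q12h is ≈ 17 mg/L, matching typical ICU troughs.
    """
    return make_model(
        "SimVanc",
        cl="0.3 + 0.044*crcl_cg",
        v="0.7*weight",
        omega_cl=0.09,
        omega_v=0.04,
        error=ErrorModel("proportional", sigma_prop=0.15),
    )


def planted_models() -> list[PKModelSpec]:
    """Three models whose predictions cross exactly at eGFR 31 and 125.

    All share V = 0.7·weight, so concentration predictions depend on CL
    alone, and the CL-vs-eGFR lines of neighbouring models intersect at the
    planted thresholds: CL = 2.8 − 0.045·eGFR crosses CL = 0.045·eGFR at
    eGFR ≈ 31, which crosses CL = 0.2·eGFR − 19.375 at eGFR = 125.  When
    each model generates the data of its own region, the best-model label
    therefore flips exactly at the thresholds.  Away from a crossing the CL
    lines diverge quickly, and IIV is kept small (ω_CL = 0.01, ω_V = 0.005),
    so subgroup membership — not individual variability — dominates which
    model predicts a patient best: the property the fixture exists to plant.
    """
    err = ErrorModel("proportional", sigma_prop=0.15)
    return [
        make_model("RenalFlat", "max(0.25, 2.8 - 0.045*egfr_ckd_epi)", "0.7*weight",
                   omega_cl=0.01, omega_v=0.005, error=err),
        make_model("RenalLinear", "0.045*egfr_ckd_epi", "0.7*weight",
                   omega_cl=0.01, omega_v=0.005, error=err),
        make_model("RenalSteep", "max(0.4, 0.2*egfr_ckd_epi - 19.375)", "0.7*weight",
                   omega_cl=0.01, omega_v=0.005, error=err),
    ]


def decoy_models() -> list[PKModelSpec]:
    """Registry padding: plausible models that are nowhere the generating one."""
    err = ErrorModel("proportional", sigma_prop=0.15)
    return [
        make_model("WeightOnly", "0.055*weight", "0.9*weight",
                   omega_cl=0.09, omega_v=0.04, error=err),
        make_model("FlatHigh", "2.8", "0.5*weight",
                   omega_cl=0.09, omega_v=0.04, error=err),
    ]


@dataclass
class SimulationConfig:
    """Study conditions for synthetic cohort generation."""

    n_patients: int = 150
    seed: int = 0
    # demographics
    male_fraction: float = 0.764
    age_median: float = 63.0
    age_sd: float = 10.0
    height_mean_male: float = 178.0
    height_mean_female: float = 165.0
    height_sd: float = 7.0
    weight_median: float = 82.0
    weight_log_sd: float = 0.22
    # renal function
    creatinine_median: float = 85.0  # µmol/L
    creatinine_log_sd: float = 0.6
    creatinine_walk_sd: float = 0.15  # daily multiplicative log-step
    creatinine_bounds: tuple[float, float] = (20.0, 800.0)
    egfr_uniform_range: tuple[float, float] | None = None  # planted scenarios
    rrt_probability: float = 0.30
    # treatment course
    duration_median_days: float = 8.0
    duration_log_sd: float = 0.45
    duration_bounds_days: tuple[int, int] = (3, 21)
    dose_amount: float = 1000.0  # mg
    infusion_duration: float = 1.0  # h
    dose_interval: float = 12.0  # h
    crcl_cutoff: float = 50.0  # mL/min, guideline branch point
    redose_trough_threshold: float = 20.0  # mg/L, low-CrCl heuristic
    # sampling
    trough_offset_range: tuple[float, float] = (0.3, 2.3)  # h before the dose
    # generating PK: regions over baseline eGFR, one model per region
    regions: tuple[tuple[float, float], ...] = ((-math.inf, math.inf),)
    models: tuple[PKModelSpec, ...] = field(default_factory=lambda: (default_generating_model(),))
    proportional_sigma: float = 0.15

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for p in (self.male_fraction, self.rrt_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probabilities must be in [0, 1], got {p}")
        if len(self.regions) != len(self.models):
            raise ValueError(
                f"{len(self.regions)} regions but {len(self.models)} models"
            )
        for (lo, hi), (lo2, _) in zip(self.regions, self.regions[1:]):
            if not (lo < hi and hi == lo2):
                raise ValueError("regions must be increasing and contiguous")
        lo0, hiN = self.regions[0][0], self.regions[-1][1]
        if not (lo0 == -math.inf or lo0 <= 0) or hiN != math.inf:
            raise ValueError("regions must cover the covariate space")


def plant_subgroup_scenario(
    thresholds: Sequence[float] = (31.0, 125.0),
    models: Sequence[PKModelSpec] | None = None,
    **overrides,
) -> SimulationConfig:
    """Config with subgroup-specific generating PK partitioned by eGFR.

    Baseline eGFR is drawn uniformly over (8, 180) so every region is
    populated, and the creatinine random walk is switched off so region
    membership is unambiguous throughout each episode.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds) or len(set(thresholds)) != len(thresholds):
        raise ValueError("thresholds must be strictly increasing")
    models = list(models) if models is not None else planted_models()
    if len(models) != len(thresholds) + 1:
        raise ValueError(
            f"{len(thresholds)} thresholds require {len(thresholds) + 1} models, "
            f"got {len(models)}"
        )
    edges = [-math.inf] + thresholds + [math.inf]
    regions = tuple((edges[i], edges[i + 1]) for i in range(len(models)))
    defaults = dict(
        regions=regions,
        models=tuple(models),
        egfr_uniform_range=(8.0, 180.0),
        creatinine_walk_sd=0.0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@dataclass(frozen=True)
class PatientTruth:
    patient_id: str
    model_name: str
    etas: IndividualParameters
    sample_times: tuple[float, ...]
    true_concentrations: tuple[float, ...]  # pre-noise


@dataclass(frozen=True)
class GroundTruth:
    patients: tuple[PatientTruth, ...]

    def model_of(self, patient_id: str) -> str:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p.model_name
        raise KeyError(patient_id)


def _creatinine_for_egfr(age: float, sex: str, target_egfr: float) -> float:
    """Invert the CKD-EPI equation numerically for a baseline creatinine."""
    return float(
        brentq(lambda scr: ckd_epi_egfr(age, sex, scr) - target_egfr, 1.0, 5000.0)
    )


def _baseline_vector(
    patient: PatientRecord, weight: float, creatinine: float
) -> CovariateVector:
    return {
        "age": patient.age,
        "sex": 1.0 if patient.sex == "male" else 0.0,
        "height": patient.height,
        "weight": weight,
        "bmi": body_mass_index(weight, patient.height),
        "creatinine": creatinine,
        "crcl_cg": cockcroft_gault_crcl(patient.age, patient.sex, patient.height, creatinine),
        "egfr_ckd_epi": ckd_epi_egfr(patient.age, patient.sex, creatinine),
        "treatment_day": 1.0,
        "rrt_active": 0.0,
    }


def guideline_dose(crcl: float) -> dict:
    """The hospital guideline dosing rule as a declarative plan.

    CrCl > 50 mL/min: 1,000 mg q12h.  CrCl ≤ 50: 1,000 mg once, later doses
    guided by troughs (here: redose when the predicted concentration falls
    below 20 mg/L).
    """
    if not crcl >= 0:
        raise ValueError(f"creatinine clearance must be non-negative, got {crcl}")
    if crcl > 50.0:
        return {"regimen": "q12h", "amount_mg": 1000.0, "interval_h": 12.0}
    return {"regimen": "trough_guided", "amount_mg": 1000.0, "trough_mg_L": 20.0}


def _simulate_episode(
    config: SimulationConfig,
    patient: PatientRecord,
    rng: np.random.Generator,
) -> tuple[TreatmentEpisode, PatientTruth]:
    # demographics already drawn; draw course-level quantities
    weight = float(
        np.exp(rng.normal(math.log(config.weight_median), config.weight_log_sd))
    )
    if config.egfr_uniform_range is not None:
        lo, hi = config.egfr_uniform_range
        crea0 = _creatinine_for_egfr(patient.age, patient.sex, float(rng.uniform(lo, hi)))
    else:
        crea0 = float(
            np.exp(rng.normal(math.log(config.creatinine_median), config.creatinine_log_sd))
        )
    crea0 = float(np.clip(crea0, *config.creatinine_bounds))

    d_lo, d_hi = config.duration_bounds_days
    n_days = int(
        np.clip(
            round(np.exp(rng.normal(math.log(config.duration_median_days), config.duration_log_sd))),
            d_lo,
            d_hi,
        )
    )
    duration_h = n_days * 24.0

    # daily creatinine trajectory (bounded geometric random walk)
    crea = [crea0]
    for _ in range(n_days):
        step = math.exp(rng.normal(0.0, config.creatinine_walk_sd))
        crea.append(float(np.clip(crea[-1] * step, *config.creatinine_bounds)))

    # generating model by baseline eGFR region
    egfr0 = ckd_epi_egfr(patient.age, patient.sex, crea0)
    region_index = next(
        i for i, (lo, hi) in enumerate(config.regions) if lo <= egfr0 < hi
    )
    spec = config.models[region_index]
    etas = IndividualParameters(
        eta_cl=float(rng.normal(0.0, math.sqrt(spec.omega_cl))) if spec.omega_cl > 0 else 0.0,
        eta_v=float(rng.normal(0.0, math.sqrt(spec.omega_v))) if spec.omega_v > 0 else 0.0,
    )
    base = _baseline_vector(patient, weight, crea0)
    tvcl, tvv = spec.typical_values(base)
    cl_i = tvcl * math.exp(etas.eta_cl)
    v_i = tvv * math.exp(etas.eta_v)

    # dosing on a 12 h grid per the guideline rule evaluated daily
    doses: list[DoseEvent] = []
    t = 0.0
    while t < duration_h:
        day = int(t // 24.0)
        crcl_t = cockcroft_gault_crcl(patient.age, patient.sex, patient.height, crea[day])
        plan = guideline_dose(crcl_t)
        give = False
        if t == 0.0:
            give = True
        elif plan["regimen"] == "q12h":
            give = True
        else:
            current = _concentration_profile(cl_i, v_i, doses, np.array([t]))[0]
            give = current < plan["trough_mg_L"]
        if give:
            doses.append(
                DoseEvent(
                    time=t,
                    amount=plan["amount_mg"],
                    infusion_duration=config.infusion_duration,
                    scheduled_time=t,
                )
            )
        t += config.dose_interval

    # trough-dominant sampling: one sample before the first dose of each day
    off_lo, off_hi = config.trough_offset_range
    sample_times: list[float] = []
    for day in range(1, n_days + 1):
        day_doses = [d for d in doses if 24.0 * day <= d.time < 24.0 * (day + 1)]
        if not day_doses:
            continue
        anchor = day_doses[0].time
        sample_times.append(anchor - float(rng.uniform(off_lo, off_hi)))
    sample_times = sorted(s for s in sample_times if s > 0)

    times = np.array(sample_times, dtype=float)
    true_conc = _concentration_profile(cl_i, v_i, doses, times)
    noise = rng.normal(0.0, config.proportional_sigma, size=times.size)
    observed = np.maximum(true_conc * (1.0 + noise), 0.05)

    observations = [
        ConcentrationObservation(time=float(ts), value=float(c))
        for ts, c in zip(times, observed)
    ]

    # covariate series: daily creatinine (lab), baseline weight (non-lab)
    series = [
        CovariateSeries(
            name="creatinine_umol_L",
            points=[(24.0 * d, c) for d, c in enumerate(crea)],
            is_lab=True,
        ),
        CovariateSeries(name="weight_kg", points=[(0.0, weight)], is_lab=False),
    ]

    rrt_intervals: list[tuple[float, float]] = []
    if rng.random() < config.rrt_probability:
        start = float(rng.uniform(0.0, min(48.0, duration_h / 2)))
        end = float(rng.uniform(start + 24.0, duration_h))
        rrt_intervals.append((start, end))

    episode = TreatmentEpisode(
        patient=patient,
        episode_id=f"{patient.patient_id}-e1",
        doses=doses,
        observations=observations,
        covariates=series,
        icu_intervals=[(0.0, duration_h + 24.0)],
        rrt_intervals=rrt_intervals,
    )
    truth = PatientTruth(
        patient_id=patient.patient_id,
        model_name=spec.name,
        etas=etas,
        sample_times=tuple(float(x) for x in times),
        true_concentrations=tuple(float(x) for x in true_conc),
    )
    return label_troughs(episode), truth


def generate_cohort(
    config: SimulationConfig, seed: int | None = None
) -> tuple[list[TreatmentEpisode], GroundTruth]:
    """Generate a reproducible synthetic cohort and its ground truth."""
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    episodes: list[TreatmentEpisode] = []
    truths: list[PatientTruth] = []
    for i in range(config.n_patients):
        sex = "male" if rng.random() < config.male_fraction else "female"
        age = float(np.clip(rng.normal(config.age_median, config.age_sd), 18.0, 95.0))
        mean_height = (
            config.height_mean_male if sex == "male" else config.height_mean_female
        )
        height = float(np.clip(rng.normal(mean_height, config.height_sd), 140.0, 210.0))
        patient = PatientRecord(
            patient_id=f"P{i + 1:04d}", sex=sex, age=age, height=height
        )
        episode, truth = _simulate_episode(config, patient, rng)
        episodes.append(episode)
        truths.append(truth)
    return episodes, GroundTruth(patients=tuple(truths))


def registry_with_decoys() -> list[PKModelSpec]:
    """The planted three-region models plus decoys, in registry order."""
    return planted_models() + decoy_models()
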