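"""Synthetic therapeutic-drug-monitoring cohorts.

Generates virtual elderly patients whose statistical structure mirrors
the study cohort the model was built on: 15 subjects aged 71-95 years,
low body weight, creatinine clearance 10.9-94.9 mL/min, once-daily
amikacin infusions of 200-1000 mg over 0.5-1 h, and sparse sampling of
two to three concentrations per subject (a peak about 1 h after the
start of an infusion and a trough just before the next dose).

Observation noise follows the assay error model: a fluorescence
polarization immunoassay with within-6% CV over the calibration range
and a 0.8 mg/L limit of detection.  Simulated concentrations below the
limit of detection are flagged and stored at LOD/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.typing import NDArray

from .pk_model import (
    DEFAULT_REFERENCE_CCR,
    CovariateModel,
    DoseEvent,
    individual_clearance,
    one_compartment_grid,
)
from .population import PopulationModel

__all__ = [
    "Covariates",
    "AssayErrorModel",
    "Subject",
    "TDMDesign",
    "STUDY_COHORT_SUMMARY",
    "derive_body_metrics",
    "cockcroft_gault",
    "sample_population",
    "simulate_tdm_cohort",
]

#: Summary statistics of the elderly cohort the generator emulates,
#: used for per-kilogram parameter reporting and design defaults.
STUDY_COHORT_SUMMARY = {
    "n_subjects": 15,
    "mean_age_y": 80.6,
    "mean_weight_kg": 44.8,
    "mean_ccr_ml_min": 52.9,
    "median_ccr_ml_min": 52.1,
    "n_observations": 33,
}


@dataclass(frozen=True)
class Covariates:
    """Demographics and renal function for one subject.

    BMI is weight/height^2; IBW = 22 * height^2 (kg); LBW by the
    sex-specific Janmahasatian formula; CCr by Cockcroft-Gault unless
    supplied directly.
    """

    age: float  # years
    sex: str  # "male" | "female"
    weight: float  # kg
    height: float  # m
    serum_creatinine: float  # mg/dL
    ccr: float  # mL/min

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex label: {self.sex!r}")
        for name in ("age", "weight", "height", "serum_creatinine", "ccr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def bmi(self) -> float:
        return self.weight / self.height**2

    @property
    def ibw(self) -> float:
        return 22.0 * self.height**2

    @property
    def lbw(self) -> float:
        _, _, lbw = derive_body_metrics(self.height, self.weight, self.sex)
        return lbw


@dataclass(frozen=True)
class AssayErrorModel:
    """Concentration-dependent observation SD with a detection limit.

    SD(C) = intercept_sd + proportional_sd * C (mg/L); observations
    below ``lod`` are reported as censored.  Defaults encode the 6%
    assay CV with a small additive floor near the 0.8 mg/L limit.
    """

    intercept_sd: float = 0.1
    proportional_sd: float = 0.06
    lod: float = 0.8

    def __post_init__(self) -> None:
        if self.intercept_sd < 0:
            raise ValueError("intercept_sd must be non-negative")
        if not 0 <= self.proportional_sd < 1:
            raise ValueError("proportional_sd must be in [0, 1)")
        if self.lod <= 0:
            raise ValueError("lod must be positive")

    def sd(self, conc: NDArray | float) -> NDArray | float:
        return self.intercept_sd + self.proportional_sd * np.asarray(conc, float)


@dataclass(frozen=True)
class Subject:
    """Dose history plus sparse concentration observations for one patient."""

    id: str
    covariates: Covariates
    doses: list[DoseEvent]
    times: NDArray[np.float64]  # observation times, h since first dose
    concentrations: NDArray[np.float64]  # mg/L
    blq: NDArray[np.bool_]  # below-limit-of-quantification flags
    #: generating (CL, V) when the subject is synthetic; None for real data
    true_params: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        b = np.asarray(self.blq, dtype=bool)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "blq", b)
        if not self.doses:
            raise ValueError("subject must have at least one dose event")
        if not (t.shape == c.shape == b.shape):
            raise ValueError("times, concentrations and blq must align")
        if t.size and t.min() < self.doses[0].start_time:
            raise ValueError("observation precedes the first dose")

    @property
    def n_obs(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class TDMDesign:
    """Sampling design and covariate ranges for cohort simulation.

    Defaults emulate the study: once-daily 30-60 min infusions of
    200-1000 mg, a peak drawn 1 h after the start of the first infusion
    and a trough 30 min before the next dose, with a third sample (peak
    after the second dose) in a fraction of subjects.  Covariates are
    drawn uniformly within the observed cohort ranges; serum creatinine
    is back-derived from the drawn CCr so that renal function and
    demographics stay mutually consistent under Cockcroft-Gault.

    ``sample_offsets_h``, when given, overrides the peak/trough rule
    with fixed observation times (h since first dose) for every subject
    — used for rich-design recovery experiments.
    """

    n_doses: int = 3
    interval_h: float = 24.0
    dose_choices_mg: tuple[float, ...] = tuple(range(200, 1001, 100))
    infusion_choices_h: tuple[float, ...] = (0.5, 1.0)
    infusion_probs: tuple[float, ...] = (2 / 3, 1 / 3)
    peak_offset_h: float = 1.0
    trough_margin_h: float = 0.5
    third_sample_prob: float = 0.2
    sample_offsets_h: tuple[float, ...] | None = None
    age_range: tuple[float, float] = (71.0, 95.0)
    weight_range: tuple[float, float] = (32.5, 67.3)
    bmi_range: tuple[float, float] = (14.9, 25.6)
    ccr_range: tuple[float, float] = (10.9, 94.9)
    female_fraction: float = 0.6  # 9 of 15 in the study


def derive_body_metrics(
    height: float, weight: float, sex: str
) -> tuple[float, float, float]:
    """BMI (kg/m^2), ideal body weight (kg) and Janmahasatian lean body
    weight (kg) from height (m), weight (kg) and sex."""
    if height <= 0 or weight <= 0:
        raise ValueError("height and weight must be positive")
    bmi = weight / height**2
    ibw = 22.0 * height**2
    if sex == "male":
        lbw = 9270.0 * weight / (6680.0 + 216.0 * bmi)
    elif sex == "female":
        lbw = 9270.0 * weight / (8780.0 + 244.0 * bmi)
    else:
        raise ValueError(f"unknown sex label: {sex!r}")
    return bmi, ibw, lbw


def cockcroft_gault(
    age: float, weight: float, serum_creatinine: float, sex: str
) -> float:
    """Cockcroft-Gault creatinine clearance, mL/min.

    (140 - age) * weight / (72 * sCr), times 0.85 for females.
    """
    if serum_creatinine <= 0 or weight <= 0:
        raise ValueError("weight and serum creatinine must be positive")
    if not 0 < age < 140:
        if age == 140:
            return 0.0
        raise ValueError("age must be in (0, 140]")
    if sex not in ("male", "female"):
        raise ValueError(f"unknown sex label: {sex!r}")
    ccr = (140.0 - age) * weight / (72.0 * serum_creatinine)
    return ccr * 0.85 if sex == "female" else ccr


def sample_population(
    pop: PopulationModel,
    covariates: list[Covariates],
    seed: int | np.random.Generator,
) -> NDArray[np.float64]:
    """Draw individual (CL, V) pairs for the given subjects.

    Between-subject variability lives on the clearance slope CLs; each
    draw is then scaled by the subject's CCr relative to the reference
    (CL_i = CLs_i * CCr_i / reference).  Returns an (n, 2) array of
    (CL, V).  Reproducible under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    params = pop.sample(len(covariates), rng)
    cls_draws, v_draws = params[:, 0], params[:, 1]
    cov_model = pop.covariate_model
    if cov_model is None:
        cl = cls_draws.copy()
    else:
        ccr = np.array([c.ccr for c in covariates])
        cl = individual_clearance(cls_draws, ccr, cov_model.reference_ccr)
    return np.column_stack([cl, v_draws])


def _draw_covariates(design: TDMDesign, rng: np.random.Generator) -> Covariates:
    age = rng.uniform(*design.age_range)
    weight = rng.uniform(*design.weight_range)
    bmi = rng.uniform(*design.bmi_range)
    height = np.sqrt(weight / bmi)
    sex = "female" if rng.random() < design.female_fraction else "male"
    ccr = rng.uniform(*design.ccr_range)
    # invert Cockcroft-Gault so sCr is consistent with the drawn CCr
    scr = (140.0 - age) * weight / (72.0 * ccr)
    if sex == "female":
        scr *= 0.85
    return Covariates(
        age=age, sex=sex, weight=weight, height=height,
        serum_creatinine=scr, ccr=ccr,
    )


def _sample_times(design: TDMDesign, rng: np.random.Generator) -> NDArray:
    if design.sample_offsets_h is not None:
        return np.asarray(design.sample_offsets_h, dtype=float)
    times = [design.peak_offset_h]
    if design.n_doses > 1:
        times.append(design.interval_h - design.trough_margin_h)
        if design.n_doses > 2 and rng.random() < design.third_sample_prob:
            times.append(design.interval_h + design.peak_offset_h)
    return np.sort(np.asarray(times, dtype=float))


def simulate_tdm_cohort(
    pop: PopulationModel,
    n_subjects: int,
    design: TDMDesign,
    error_model: AssayErrorModel,
    seed: int | np.random.Generator,
) -> list[Subject]:
    """Simulate a sparse-sampling TDM cohort from a population model.

    Noise-free predictions from the one-compartment model are perturbed
    with N(0, SD(C)^2) assay noise; negative results are resampled.
    Concentrations below the limit of detection are flagged and stored
    at LOD/2.
    """
    rng = np.random.default_rng(seed)
    subjects: list[Subject] = []
    for i in range(n_subjects):
        cov = _draw_covariates(design, rng)
        params = sample_population(pop, [cov], rng)
        cl, v = float(params[0, 0]), float(params[0, 1])
        dose_mg = float(rng.choice(design.dose_choices_mg))
        inf_h = float(
            rng.choice(design.infusion_choices_h, p=design.infusion_probs)
        )
        doses = [
            DoseEvent(start_time=k * design.interval_h, amount=dose_mg,
                      infusion_duration=inf_h)
            for k in range(design.n_doses)
        ]
        times = _sample_times(design, rng)
        pred = one_compartment_grid(np.array([cl]), np.array([v]), doses, times)[0]
        sd = np.asarray(error_model.sd(pred), dtype=float)
        obs = pred + rng.normal(0.0, 1.0, size=pred.shape) * sd
        neg = obs < 0
        while neg.any():  # truncate: resample negative assay results
            obs[neg] = pred[neg] + rng.normal(0.0, 1.0, size=int(neg.sum())) * sd[neg]
            neg = obs < 0
        blq = obs < error_model.lod
        obs = np.where(blq, error_model.lod / 2.0, obs)
        subjects.append(
            Subject(id=f"S{i + 1:03d}", covariates=cov, doses=doses,
                    times=times, concentrations=obs, blq=blq,
                    true_params=(cl, v))
        )
    return subjects
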