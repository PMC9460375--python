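"""Synthetic longitudinal cohorts with the study's structure.

The source cohort is not deposited, so every downstream module is
exercised on simulated data: 374 patients of both sexes aged 7-73, with
4-8 monthly body-mass controls each, masses quantised to the 0.1 kg
resolution of a clinical balance, and pathophysiology groups dominated by
healthy subjects with small anorexia and tumor groups.

Trajectories are generated from the composite three-phase equation with
per-patient ground-truth parameters, additive Gaussian measurement noise
and quantisation. Daily food mass is derived from the trajectory through
the metabolic-constant formula: the first visit's food reflects the
subject's habitual intake (initial constant k_mi), later visits the
assigned diet that drives the final constant k_mf — so the endpoint
metabolic constants recomputed from the records match the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fitting import PatientSeries
from .model import (
    CompositeParams,
    composite_mass,
    food_mass_from_constant,
    metabolic_constant,
)

__all__ = ["CohortConfig", "TrueParams", "simulate_patient", "simulate_cohort"]

_DEFAULT_GROUP_WEIGHTS = {
    "healthy": 0.70,
    "anorexia": 0.025,
    "tumors": 0.03,
    "other": 0.245,
}

# Initial-BMI sampling ranges (kg/m^2) by pathophysiology group.
_BMI_RANGES = {
    "healthy": (18.5, 30.0),
    "anorexia": (13.0, 17.5),
    "tumors": (16.0, 28.0),
    "other": (17.0, 32.0),
}

_NORMAL_BMI = (18.5, 25.0)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-generation settings.

    Defaults mirror the study design: 374 patients aged 7-73, at least
    four monthly controls, balance resolution 0.1 kg. ``noise_sd`` is the
    measurement-noise standard deviation (kg); 0.25 kg keeps the expected
    per-patient variance (~0.0625 kg^2) well inside the validity regime.
    """

    n_patients: int = 374
    age_range: tuple[int, int] = (7, 73)
    group_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_GROUP_WEIGHTS)
    )
    visits_range: tuple[int, int] = (4, 8)
    visit_interval_days: float = 30.0
    noise_sd: float = 0.25
    balance_resolution: float = 0.1
    food_mass_range: tuple[float, float] = (1.0, 3.0)
    alpha_range: tuple[float, float] = (5e-4, 5e-3)
    beta_ratio_range: tuple[float, float] = (1.5, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.visits_range[0] < 4 or self.visits_range[1] < self.visits_range[0]:
            raise ValueError("visits_range must be ordered with minimum >= 4")
        if self.noise_sd < 0.0:
            raise ValueError("noise_sd must be >= 0")
        if self.balance_resolution < 0.0:
            raise ValueError("balance_resolution must be >= 0")
        if self.visit_interval_days <= 0.0:
            raise ValueError("visit_interval_days must be > 0")
        total = sum(self.group_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"group weights must sum to 1, got {total}")
        if not (self.age_range[0] < self.age_range[1]):
            raise ValueError("age_range must be ordered")


@dataclass(frozen=True)
class TrueParams:
    """Ground-truth parameters and demographics behind one simulated patient."""

    patient_id: str
    params: CompositeParams
    sex: str
    age: int
    height: float
    group: str


def _sample_height(rng: np.random.Generator, age: int, sex: str) -> float:
    """Height (m): adult sex-specific normal, children interpolated toward it."""
    adult_mu = 1.75 if sex == "M" else 1.62
    adult_sd = 0.07 if sex == "M" else 0.065
    adult = rng.normal(adult_mu, adult_sd)
    if age >= 18:
        h = adult
    else:
        frac = (age - 7) / 11.0  # linear growth proxy from age 7 to 18
        h = 1.20 + frac * (adult - 1.20)
    return float(np.clip(h, 1.0, 2.1))


def _sample_truth(rng: np.random.Generator, pid: str, config: CohortConfig) -> TrueParams:
    groups = list(config.group_weights)
    weights = np.array([config.group_weights[g] for g in groups])
    group = str(rng.choice(groups, p=weights / weights.sum()))
    sex = "M" if rng.random() < 0.5 else "F"
    age = int(rng.integers(config.age_range[0], config.age_range[1] + 1))
    height = _sample_height(rng, age, sex)

    lo, hi = _BMI_RANGES.get(group, _BMI_RANGES["other"])
    bmi_i = rng.uniform(lo, hi)
    # the assigned diet pulls the subject toward the normal BMI interval
    bmi_target = float(np.clip(bmi_i, *_NORMAL_BMI))
    bmi_f = bmi_i + rng.uniform(0.5, 1.0) * (bmi_target - bmi_i)
    if abs(bmi_f - bmi_i) < 0.25:  # already normal: small drift, not identical
        bmi_f = bmi_i + rng.uniform(-0.75, 0.75)
    M_i = bmi_i * height**2
    M_f = max(bmi_f * height**2, 0.5 * M_i)

    food_i = rng.uniform(*config.food_mass_range)
    food_f = rng.uniform(*config.food_mass_range)
    k_mi = metabolic_constant(M_i, min(food_i, 0.5 * M_i))
    k_mf = metabolic_constant(M_f, min(food_f, 0.5 * M_f))

    a_lo, a_hi = config.alpha_range
    alpha = float(np.exp(rng.uniform(np.log(a_lo), np.log(a_hi))))
    beta = alpha * float(rng.uniform(*config.beta_ratio_range))
    params = CompositeParams(M_i=M_i, M_f=M_f, k_mi=k_mi, k_mf=k_mf, alpha=alpha, beta=beta)
    return TrueParams(patient_id=pid, params=params, sex=sex, age=age, height=height, group=group)


def simulate_patient(
    truth: TrueParams,
    schedule,
    noise_sd: float = 0.25,
    resolution: float = 0.1,
    seed: int | np.random.Generator = 0,
    max_retries: int = 100,
) -> PatientSeries:
    """One patient's record from ground truth on a visit schedule (hours).

    Observed masses are the composite trajectory plus Gaussian noise,
    rounded to the balance resolution; non-positive draws are resampled
    (bounded retries). Food mass at the first visit comes from the initial
    metabolic constant, at later visits from the final one, both through
    the food-mass inverse of the k_m formula applied to the true
    (noise-free) trajectory.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.asarray(schedule, dtype=float)
    if t.size < 4 or t[0] != 0.0 or not np.all(np.diff(t) > 0.0):
        raise ValueError("schedule must start at 0, be increasing, with >= 4 visits")
    clean = np.asarray(composite_mass(truth.params, t), dtype=float)
    masses = clean.copy()
    if noise_sd > 0.0:
        for i in range(t.size):
            for attempt in range(max_retries + 1):
                m = clean[i] + rng.normal(0.0, noise_sd)
                if m > 0.0:
                    masses[i] = m
                    break
            else:
                raise RuntimeError("could not draw a positive body mass")
    if resolution > 0.0:
        masses = np.round(masses / resolution) * resolution
    food = np.empty_like(clean)
    food[0] = food_mass_from_constant(clean[0], truth.params.k_mi)
    food[1:] = [food_mass_from_constant(m, truth.params.k_mf) for m in clean[1:]]
    return PatientSeries(
        patient_id=truth.patient_id,
        times=t,
        masses=masses,
        food_mass=food,
        sex=truth.sex,
        age=truth.age,
        height=truth.height,
        group=truth.group,
    )


def simulate_cohort(config: CohortConfig | None = None) -> tuple[list[PatientSeries], list[TrueParams]]:
    """Generate a full cohort; returns (series, ground truths).

    Deterministic given ``config.seed``: the same seed yields identical
    cohorts element for element.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    series: list[PatientSeries] = []
    truths: list[TrueParams] = []
    width = len(str(config.n_patients))
    for i in range(config.n_patients):
        pid = f"P{i + 1:0{width}d}"
        truth = _sample_truth(rng, pid, config)
        n_visits = int(rng.integers(config.visits_range[0], config.visits_range[1] + 1))
        schedule = np.arange(n_visits) * config.visit_interval_days * 24.0
        series.append(
            simulate_patient(
                truth,
                schedule,
                noise_sd=config.noise_sd,
                resolution=config.balance_resolution,
                seed=rng,
            )
        )
        truths.append(truth)
    return series, truths
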