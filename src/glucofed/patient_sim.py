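"""Virtual type 1 diabetes patients: cohort sampling, glucose-insulin dynamics, meals, CGM.

The dynamics are a Bergman-minimal-class ODE system per patient:

    dG/dt  = EGP - (S_G + X) * G + k_abs * Q2 / V_G        plasma glucose, mg/dL
    dX/dt  = k_a * (beta_I * I - X)                        remote insulin effect, 1/min
    dI/dt  = -k_e * I + u / 60                             plasma insulin, U (scaled)
    dQ1/dt = -k_abs * Q1                                   gut compartment 1, mg
    dQ2/dt = k_abs * (Q1 - Q2)                             gut compartment 2, mg
    dGi/dt = (G - Gi) / tau_cgm                            interstitial glucose, mg/dL

where u is the insulin infusion rate in U/h, V_G the glucose distribution
volume (1.7 dL/kg of body weight) and beta_I the insulin action gain derived
from the patient's steady-state insulin sensitivity.  Endogenous glucose
production is pinned at sampling time so that (G, X, I) = (target basal
glucose, beta_I * I_b, I_b) is an exact equilibrium under the basal infusion
rate.  Integration is fixed-step classical Runge-Kutta with 1-minute substeps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .exceptions import ConfigError, NumericsError, ValidationError

COHORTS = ("child", "adolescent", "adult")

#: CGM sensor reporting range, mg/dL.
CGM_MIN, CGM_MAX = 39.0, 400.0

#: Hard physiologic floor applied to integrated plasma glucose, mg/dL.
GLUCOSE_FLOOR = 20.0

#: Glucose distribution volume per kg of body weight, dL/kg.
GLUCOSE_VOLUME_PER_KG = 1.7

#: Default interstitial (CGM) lag time constant, minutes.
DEFAULT_CGM_LAG_MIN = 10.0

#: Default CGM additive noise SD, mg/dL.
DEFAULT_CGM_NOISE_SD = 5.0

# Per-cohort uniform sampling ranges.  Children have lower body weight and
# faster carbohydrate absorption (higher glycemic variability) than adults;
# basal requirements scale roughly with weight.  `insulin_drive_ratio` is the
# ratio of insulin-mediated to insulin-independent glucose clearance at basal,
# which fixes insulin sensitivity and endogenous production jointly (see
# docs/methods.md).
COHORT_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "child": {
        "body_weight": (25.0, 45.0),
        "basal_rate": (0.30, 0.60),
        "glucose_effectiveness": (0.0035, 0.0060),
        "insulin_action_rate": (0.015, 0.030),
        "insulin_clearance_rate": (0.10, 0.18),
        "carb_absorption_rate": (0.025, 0.040),
        "carb_bioavailability": (0.75, 0.90),
        "target_basal_glucose": (120.0, 140.0),
        "insulin_drive_ratio": (1.00, 1.30),
    },
    "adolescent": {
        "body_weight": (45.0, 70.0),
        "basal_rate": (0.60, 1.00),
        "glucose_effectiveness": (0.0030, 0.0050),
        "insulin_action_rate": (0.012, 0.025),
        "insulin_clearance_rate": (0.10, 0.18),
        "carb_absorption_rate": (0.020, 0.035),
        "carb_bioavailability": (0.75, 0.90),
        "target_basal_glucose": (115.0, 135.0),
        "insulin_drive_ratio": (1.10, 1.40),
    },
    "adult": {
        "body_weight": (60.0, 95.0),
        "basal_rate": (0.80, 1.40),
        "glucose_effectiveness": (0.0035, 0.0060),
        "insulin_action_rate": (0.015, 0.030),
        "insulin_clearance_rate": (0.10, 0.18),
        "carb_absorption_rate": (0.015, 0.030),
        "carb_bioavailability": (0.75, 0.90),
        "target_basal_glucose": (115.0, 135.0),
        "insulin_drive_ratio": (1.00, 1.35),
    },
}


@dataclass(frozen=True)
class PatientParams:
    """Physiology of one simulated patient.

    ``insulin_sensitivity`` is the steady-state plasma-glucose drop (mg/dL)
    per unit increase of the (scaled) plasma-insulin compartment, linearized
    at basal.  ``endogenous_production`` (mg/dL/min) is chosen at sampling
    time so the basal infusion rate holds glucose at
    ``target_basal_glucose`` exactly.
    """

    patient_id: str
    cohort: str
    body_weight: float            # kg
    basal_rate: float             # U/h
    insulin_sensitivity: float    # (mg/dL) per U
    glucose_effectiveness: float  # 1/min
    insulin_action_rate: float    # 1/min
    insulin_clearance_rate: float # 1/min
    carb_absorption_rate: float   # 1/min
    carb_bioavailability: float   # fraction in (0, 1]
    endogenous_production: float  # mg/dL/min
    target_basal_glucose: float   # mg/dL

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ConfigError(f"unknown cohort {self.cohort!r}; expected one of {COHORTS}")
        for name in (
            "body_weight", "basal_rate", "insulin_sensitivity", "glucose_effectiveness",
            "insulin_action_rate", "insulin_clearance_rate", "carb_absorption_rate",
            "endogenous_production", "target_basal_glucose",
        ):
            if not getattr(self, name) > 0:
                raise ConfigError(f"PatientParams.{name} must be strictly positive")
        if not (0.0 < self.carb_bioavailability <= 1.0):
            raise ConfigError("PatientParams.carb_bioavailability must lie in (0, 1]")

    @property
    def basal_plasma_insulin(self) -> float:
        """Steady-state plasma insulin (scaled U) under the basal rate."""
        return self.basal_rate / (60.0 * self.insulin_clearance_rate)

    @property
    def insulin_action_gain(self) -> float:
        """beta_I in 1/(U*min): remote-effect level per unit plasma insulin."""
        return (
            self.insulin_sensitivity
            * self.endogenous_production
            / self.target_basal_glucose ** 2
        )

    @property
    def glucose_volume_dl(self) -> float:
        return GLUCOSE_VOLUME_PER_KG * self.body_weight


@dataclass(frozen=True)
class SimState:
    """Full simulator state (the hidden POMDP state)."""

    t: float                     # minutes since episode start
    plasma_glucose: float        # mg/dL
    remote_insulin_effect: float # 1/min
    plasma_insulin: float        # U (scaled)
    gut_carb_1: float            # mg
    gut_carb_2: float            # mg
    interstitial_glucose: float  # mg/dL

    _FIELDS = (
        "t", "plasma_glucose", "remote_insulin_effect", "plasma_insulin",
        "gut_carb_1", "gut_carb_2", "interstitial_glucose",
    )

    def as_vector(self) -> np.ndarray:
        return np.array([
            self.plasma_glucose, self.remote_insulin_effect, self.plasma_insulin,
            self.gut_carb_1, self.gut_carb_2, self.interstitial_glucose,
        ])


@dataclass(frozen=True)
class MealEvent:
    time: float   # minutes
    carbs: float  # grams

    def __post_init__(self) -> None:
        if self.carbs < 0:
            raise ValidationError("MealEvent.carbs must be >= 0")


@dataclass(frozen=True)
class CGMReading:
    t: float
    value: float  # mg/dL, clamped to [CGM_MIN, CGM_MAX]


def make_cohort(cohort: str, n: int, seed: int) -> list[PatientParams]:
    """Draw ``n`` heterogeneous patients from a cohort's parameter ranges.

    Reproducible: the same (cohort, n, seed) yields field-identical patients.
    """
    if cohort not in COHORT_RANGES:
        raise ConfigError(f"unknown cohort {cohort!r}; expected one of {COHORTS}")
    if n < 0:
        raise ConfigError("n must be >= 0")
    rng = np.random.default_rng(seed)
    ranges = COHORT_RANGES[cohort]
    patients = []
    for i in range(n):
        draw = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in ranges.items()}
        ratio = draw.pop("insulin_drive_ratio")
        g_b = draw["target_basal_glucose"]
        s_g = draw["glucose_effectiveness"]
        i_b = draw["basal_rate"] / (60.0 * draw["insulin_clearance_rate"])
        # Pin endogenous production so basal is an exact equilibrium, and set
        # the sensitivity so insulin-mediated clearance at basal is `ratio`
        # times the insulin-independent clearance.
        egp = g_b * s_g * (1.0 + ratio)
        q = ratio / (1.0 + ratio)
        s_i = q * g_b / i_b
        patients.append(PatientParams(
            patient_id=f"{cohort}#{i + 1:03d}",
            cohort=cohort,
            insulin_sensitivity=s_i,
            endogenous_production=egp,
            **draw,
        ))
    return patients


def equilibrium_state(params: PatientParams, t: float = 0.0,
                      plasma_glucose: float | None = None) -> SimState:
    """Basal steady state; optionally start glucose away from equilibrium."""
    g = params.target_basal_glucose if plasma_glucose is None else float(plasma_glucose)
    i_b = params.basal_plasma_insulin
    return SimState(
        t=t,
        plasma_glucose=g,
        remote_insulin_effect=params.insulin_action_gain * i_b,
        plasma_insulin=i_b,
        gut_carb_1=0.0,
        gut_carb_2=0.0,
        interstitial_glucose=g,
    )


def _rhs(y: np.ndarray, params: PatientParams, insulin_rate: float,
         cgm_lag_min: float) -> np.ndarray:
    g, x, ins, q1, q2, gi = y
    ra = params.carb_absorption_rate * q2 / params.glucose_volume_dl
    dg = params.endogenous_production - (params.glucose_effectiveness + x) * g + ra
    dx = params.insulin_action_rate * (params.insulin_action_gain * ins - x)
    di = -params.insulin_clearance_rate * ins + insulin_rate / 60.0
    dq1 = -params.carb_absorption_rate * q1
    dq2 = params.carb_absorption_rate * (q1 - q2)
    dgi = 0.0 if cgm_lag_min <= 1e-9 else (g - gi) / cgm_lag_min
    return np.array([dg, dx, di, dq1, dq2, dgi])


def step_dynamics(state: SimState, params: PatientParams, insulin_rate: float,
                  dt: float, substep: float = 1.0,
                  cgm_lag_min: float = DEFAULT_CGM_LAG_MIN) -> SimState:
    """Advance the ODE system by ``dt`` minutes with RK4 substeps.

    Deterministic.  Plasma glucose is floored at ``GLUCOSE_FLOOR`` and the
    gut compartments at zero after each substep.
    """
    if dt <= 0:
        raise ValidationError("dt must be > 0")
    if insulin_rate < 0:
        raise ValidationError("insulin_rate must be >= 0")
    y = state.as_vector()
    for name, v in zip(SimState._FIELDS[1:], y):
        if not np.isfinite(v):
            raise NumericsError(f"non-finite state entry: {name}")
    n = max(1, int(round(dt / substep)))
    h = dt / n
    for _ in range(n):
        k1 = _rhs(y, params, insulin_rate, cgm_lag_min)
        k2 = _rhs(y + 0.5 * h * k1, params, insulin_rate, cgm_lag_min)
        k3 = _rhs(y + 0.5 * h * k2, params, insulin_rate, cgm_lag_min)
        k4 = _rhs(y + h * k3, params, insulin_rate, cgm_lag_min)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        y[0] = max(y[0], GLUCOSE_FLOOR)
        y[3] = max(y[3], 0.0)
        y[4] = max(y[4], 0.0)
    if cgm_lag_min <= 1e-9:
        y[5] = y[0]
    if not np.all(np.isfinite(y)):
        bad = SimState._FIELDS[1:][int(np.argmax(~np.isfinite(y)))]
        raise NumericsError(f"integration produced non-finite value in {bad}")
    return SimState(state.t + dt, *map(float, y))


def apply_meal(state: SimState, meal: MealEvent, params: PatientParams) -> SimState:
    """Deposit a meal's bioavailable carbohydrate (mg) into gut compartment 1."""
    if meal.carbs < 0:
        raise ValidationError("meal carbs must be >= 0")
    deposit = meal.carbs * 1000.0 * params.carb_bioavailability
    return replace(state, gut_carb_1=state.gut_carb_1 + deposit)


def sense_cgm(state: SimState, noise_sd: float, rng: np.random.Generator) -> CGMReading:
    """One CGM sample: lagged interstitial glucose + Gaussian noise, clamped."""
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    value = state.interstitial_glucose
    if noise_sd > 0:
        value += noise_sd * rng.standard_normal()
    return CGMReading(t=state.t, value=float(np.clip(value, CGM_MIN, CGM_MAX)))


def make_scenario(days: int, meals_per_day: int, seed: int, *,
                  window_start: float = 360.0, window_end: float = 1260.0,
                  carb_range: tuple[float, float] = (40.0, 70.0)) -> list[MealEvent]:
    """Randomized daily meal schedule over ``days`` days.

    Each day the eating window [window_start, window_end] (minutes of day) is
    split into equal slots, one meal placed uniformly inside the middle 80% of
    each slot, with carbs drawn uniformly from ``carb_range``.  Reproducible
    given the seed; times are strictly increasing.
    """
    if days < 1:
        raise ValidationError("days must be >= 1")
    if meals_per_day < 0:
        raise ValidationError("meals_per_day must be >= 0")
    rng = np.random.default_rng(seed)
    meals: list[MealEvent] = []
    if meals_per_day == 0:
        return meals
    slot = (window_end - window_start) / meals_per_day
    for day in range(days):
        base = day * 1440.0
        for m in range(meals_per_day):
            lo = window_start + m * slot + 0.1 * slot
            hi = window_start + (m + 1) * slot - 0.1 * slot
            t = base + rng.uniform(lo, hi)
            carbs = rng.uniform(*carb_range)
            meals.append(MealEvent(time=float(t), carbs=float(carbs)))
    return meals


def scenario_to_frame(meals: Sequence[MealEvent]):
    """Meal list as a pandas DataFrame (time_min, carbs_g)."""
    import pandas as pd

    return pd.DataFrame({
        "time_min": [m.time for m in meals],
        "carbs_g": [m.carbs for m in meals],
    })
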