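"""Partially observable closed-loop control environment around a virtual patient.

One decision step = 5 simulated minutes; a 5-day episode = 1440 steps.  The
agent observes only CGM readings (noisy, lagged), its own delivered insulin,
announced meal carbohydrates, and clock time — never plasma glucose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import patient_sim as ps
from .exceptions import EpisodeStateError, ValidationError
from .reward import RewardBreakdown, RewardConfig, compute_reward, validate_config, with_pump_limit

#: Pump safety cap: maximum basal rate as a multiple of the patient's
#: programmed basal (the common "200% temporary basal" limit).
MAX_RATE_BASAL_MULTIPLE = 2.0

STEP_MINUTES = 5.0
STEPS_PER_DAY = 288


@dataclass(frozen=True)
class Observation:
    """What the controller sees: k-step histories plus clock time."""

    cgm_history: np.ndarray      # mg/dL, oldest first
    insulin_history: np.ndarray  # U/h delivered
    carb_history: np.ndarray     # g announced at delivery
    time_of_day: float           # minutes mod 1440

    @property
    def k(self) -> int:
        return len(self.cgm_history)


@dataclass(frozen=True)
class InsulinAction:
    rate: float  # U/h


@dataclass
class EpisodeTrace:
    """Per-step arrays for one episode; one row per 5-minute step."""

    t_min: list = field(default_factory=list)
    plasma_glucose: list = field(default_factory=list)
    cgm: list = field(default_factory=list)
    insulin_rate: list = field(default_factory=list)
    carbs: list = field(default_factory=list)
    reward: list = field(default_factory=list)
    deviation_term: list = field(default_factory=list)
    insulin_term: list = field(default_factory=list)
    stability_term: list = field(default_factory=list)
    risk_term: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.t_min)

    def append(self, t, g, cgm, rate, carbs, rb: RewardBreakdown) -> None:
        self.t_min.append(t)
        self.plasma_glucose.append(g)
        self.cgm.append(cgm)
        self.insulin_rate.append(rate)
        self.carbs.append(carbs)
        self.reward.append(rb.total)
        self.deviation_term.append(rb.deviation_term)
        self.insulin_term.append(rb.insulin_term)
        self.stability_term.append(rb.stability_term)
        self.risk_term.append(rb.risk_term)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({k: getattr(self, k) for k in (
            "t_min", "plasma_glucose", "cgm", "insulin_rate", "carbs", "reward",
            "deviation_term", "insulin_term", "stability_term", "risk_term")})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EpisodeTrace":
        frame = pd.read_csv(path)
        trace = cls()
        for k in trace.__dict__:
            setattr(trace, k, frame[k].tolist())
        return trace


class GlucoseEnv:
    """Episodic reset/step environment for one patient and meal scenario."""

    def __init__(self, patient: ps.PatientParams,
                 scenario: list[ps.MealEvent] | None = None,
                 reward_config: RewardConfig | None = None,
                 days: int = 5, k_history: int = 12,
                 cgm_noise_sd: float = ps.DEFAULT_CGM_NOISE_SD,
                 cgm_lag_min: float = ps.DEFAULT_CGM_LAG_MIN,
                 max_rate: float | None = None,
                 init_glucose_jitter: float = 20.0,
                 substep: float = 1.0):
        self.patient = patient
        self.scenario = list(scenario or [])
        self.days = int(days)
        self.n_steps = self.days * STEPS_PER_DAY
        self.k = int(k_history)
        self.cgm_noise_sd = float(cgm_noise_sd)
        self.cgm_lag_min = float(cgm_lag_min)
        self.max_rate = float(max_rate if max_rate is not None
                              else MAX_RATE_BASAL_MULTIPLE * patient.basal_rate)
        self.init_glucose_jitter = float(init_glucose_jitter)
        self.substep = float(substep)
        self.reward_config = with_pump_limit(
            validate_config(reward_config), self.max_rate)
        self._state: ps.SimState | None = None
        self._done = True
        self.trace: EpisodeTrace | None = None

    # -- episode control ----------------------------------------------------

    def reset(self, seed: int, patient: ps.PatientParams | None = None,
              scenario: list[ps.MealEvent] | None = None) -> Observation:
        """Start a new episode at a (jittered) basal equilibrium."""
        if patient is not None:
            self.patient = patient
            self.max_rate = MAX_RATE_BASAL_MULTIPLE * patient.basal_rate
            self.reward_config = with_pump_limit(self.reward_config, self.max_rate)
        if scenario is not None:
            self.scenario = list(scenario)
        horizon = self.n_steps * STEP_MINUTES
        for meal in self.scenario:
            if meal.time >= horizon:
                raise ValidationError(
                    f"meal at t={meal.time} min exceeds episode horizon {horizon} min")
        self._rng = np.random.default_rng(seed)
        g0 = self.patient.target_basal_glucose
        if self.init_glucose_jitter > 0:
            g0 += float(self._rng.uniform(-1, 1)) * self.init_glucose_jitter
        self._state = ps.equilibrium_state(self.patient, plasma_glucose=g0)
        self._meals = sorted(self.scenario, key=lambda m: m.time)
        self._next_meal = 0
        self._step_count = 0
        self._done = False
        self.trace = EpisodeTrace()
        reading = ps.sense_cgm(self._state, self.cgm_noise_sd, self._rng)
        self._cgm_hist = [reading.value] * self.k
        self._ins_hist = [self.patient.basal_rate] * self.k
        self._carb_hist = [0.0] * self.k
        self._last_cgm = reading.value
        return self._observation()

    def _observation(self) -> Observation:
        return Observation(
            cgm_history=np.array(self._cgm_hist),
            insulin_history=np.array(self._ins_hist),
            carb_history=np.array(self._carb_hist),
            time_of_day=float(self._state.t % 1440.0),
        )

    def step(self, action: InsulinAction | float):
        """Advance 5 minutes under the given basal rate.

        Returns ``(observation, reward, done, info)``; ``info`` carries the
        reward breakdown, a state snapshot, and an action-clipped flag.
        """
        if self._done or self._state is None:
            raise EpisodeStateError("step() called before reset() or after done")
        rate_req = float(getattr(action, "rate", action))
        rate = float(np.clip(rate_req, 0.0, self.max_rate))
        clipped = rate != rate_req

        state = self._state
        t0, t1 = state.t, state.t + STEP_MINUTES
        carbs_now = 0.0
        while self._next_meal < len(self._meals) and self._meals[self._next_meal].time < t1:
            meal = self._meals[self._next_meal]
            if meal.time >= t0:
                state = ps.apply_meal(state, meal, self.patient)
                carbs_now += meal.carbs
            self._next_meal += 1

        prev_bg = state.plasma_glucose
        state = ps.step_dynamics(state, self.patient, rate, STEP_MINUTES,
                                 substep=self.substep, cgm_lag_min=self.cgm_lag_min)
        reading = ps.sense_cgm(state, self.cgm_noise_sd, self._rng)
        prev_obs = self._observation()
        breakdown = compute_reward(prev_obs, InsulinAction(rate),
                                   state.plasma_glucose, prev_bg, self.reward_config)

        self._state = state
        self._cgm_hist = self._cgm_hist[1:] + [reading.value]
        self._ins_hist = self._ins_hist[1:] + [rate]
        self._carb_hist = self._carb_hist[1:] + [carbs_now]
        self._last_cgm = reading.value
        self._step_count += 1
        self._done = self._step_count >= self.n_steps
        self.trace.append(state.t, state.plasma_glucose, reading.value, rate,
                          carbs_now, breakdown)
        info = {"breakdown": breakdown, "state": state, "clipped": clipped,
                "carbs": carbs_now}
        return self._observation(), breakdown.total, self._done, info

    @property
    def done(self) -> bool:
        return self._done


def run_constant_basal(env: GlucoseEnv, seed: int,
                       rate: float | None = None) -> EpisodeTrace:
    """Roll one episode under a constant basal rate (baseline controller)."""
    env.reset(seed)
    r = env.patient.basal_rate if rate is None else rate
    done = False
    while not done:
        _, _, done, _ = env.step(InsulinAction(r))
    return env.trace
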