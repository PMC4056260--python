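"""Virtual critically ill patient: glucose-insulin compartment kinetics.

The physiology is a two-compartment glucose model (accessible mass ``Q1``,
non-accessible mass ``Q2``) with three remote insulin actions acting on
glucose transport (``x1``), disposal (``x2``) and suppression of endogenous
glucose production (``x3``), plus a single plasma-insulin compartment and a
first-order gut compartment delaying enteral carbohydrate appearance.
Plasma glucose is ``G = Q1 / (V_G * weight)`` in mM.

Insulin sensitivity is modulated by a smooth, bounded, time-varying
``resistance_profile`` emulating circadian/stress variation in the critically
ill; steroid episodes multiply on top of it.

All parameter values are implementation-chosen nominal constants (the model
family is standard; the exact clinical controller's internal parameters are
not public) and are sampled log-normally across a cohort.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "MMOL_PER_G",
    "DEXTROSE_G_PER_ML",
    "NOMINAL",
    "PatientParams",
    "PatientState",
    "ExogenousInput",
    "ConstantResistance",
    "SinusoidResistance",
    "EpisodeResistance",
    "ProductResistance",
    "ArrayResistance",
    "NoEquilibriumError",
    "DegenerateStateError",
    "nominal_params",
    "derivatives",
    "step",
    "steady_state",
    "steady_state_glucose",
    "basal_for_glucose",
    "CohortConfig",
    "make_cohort",
    "trajectory_frame",
]

logger = logging.getLogger(__name__)

#: mmol of glucose per gram (molar mass 180.16 g/mol).
MMOL_PER_G = 5.551
#: 20% dextrose solution carries 0.2 g glucose per mL.
DEXTROSE_G_PER_ML = 0.20

#: Resistance profile clamp, dimensionless.
RESISTANCE_BOUNDS = (0.2, 3.0)


class NoEquilibriumError(ValueError):
    """Raised when the model admits no positive steady-state glucose."""


class DegenerateStateError(ValueError):
    """Raised when a state vector contains non-finite components."""


# ---------------------------------------------------------------------------
# resistance profiles


def _clip_resistance(v: float) -> float:
    lo, hi = RESISTANCE_BOUNDS
    return min(max(v, lo), hi)


@dataclass(frozen=True)
class ConstantResistance:
    value: float = 1.0

    def __call__(self, t: float) -> float:
        return _clip_resistance(self.value)


@dataclass(frozen=True)
class SinusoidResistance:
    """Smooth periodic insulin-sensitivity modulation, mean 1."""

    amplitude: float = 0.2
    period_min: float = 480.0
    phase: float = 0.0

    def __call__(self, t: float) -> float:
        v = 1.0 + self.amplitude * math.sin(2.0 * math.pi * t / self.period_min + self.phase)
        return _clip_resistance(v)


@dataclass(frozen=True)
class EpisodeResistance:
    """Multiplicative episode (e.g. corticosteroid course) of fixed duration."""

    start_min: float
    duration_min: float
    factor: float = 1.5

    def __call__(self, t: float) -> float:
        if self.start_min <= t < self.start_min + self.duration_min:
            return _clip_resistance(self.factor)
        return 1.0


@dataclass(frozen=True)
class ProductResistance:
    parts: tuple

    def __call__(self, t: float) -> float:
        v = 1.0
        for p in self.parts:
            v *= p(t)
        return _clip_resistance(v)


@dataclass(frozen=True)
class ArrayResistance:
    """Per-minute lookup profile (zero-order hold)."""

    values: tuple

    def __call__(self, t: float) -> float:
        i = int(t)
        i = min(max(i, 0), len(self.values) - 1)
        return _clip_resistance(self.values[i])


# ---------------------------------------------------------------------------
# parameter / state containers


@dataclass
class PatientParams:
    """True physiology of one virtual subject.

    Rates are per minute, volumes per kg; insulin sensitivities are per
    (mU/L) scaled activation gains of the three remote actions.
    """

    weight: float  # kg
    V_G: float  # L/kg, glucose distribution volume
    k12: float  # 1/min, accessible <-> non-accessible transfer
    F01: float  # mmol/kg/min, non-insulin-dependent flux
    EGP0: float  # mmol/kg/min, endogenous production at zero insulin action
    V_I: float  # L/kg, insulin distribution volume
    k_e: float  # 1/min, plasma insulin elimination
    k_a1: float
    k_a2: float
    k_a3: float
    S_IT: float
    S_ID: float
    S_IE: float
    gut_tau: float = 40.0  # min, enteral appearance delay
    resistance_profile: Callable[[float], float] = field(default_factory=ConstantResistance)
    diabetes: bool = False
    apache2: float = 12.0
    bmi: float = 28.0
    # cohort annotations: the basal insulin and the steady glucose it maintains
    basal_insulin: float = 1.0  # U/h
    baseline_glucose: float = 10.5  # mM
    subject_id: int = 0

    def __post_init__(self) -> None:
        for name in ("V_G", "k12", "F01", "EGP0", "V_I", "k_e", "k_a1", "k_a2", "k_a3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("S_IT", "S_ID", "S_IE"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (40.0 <= self.weight <= 200.0):
            raise ValueError("weight must lie in [40, 200] kg")
        if self.gut_tau <= 0:
            raise ValueError("gut_tau must be positive")


@dataclass
class PatientState:
    """Instantaneous model state; ``gut`` is the enteral glucose in transit."""

    Q1: float  # mmol
    Q2: float  # mmol
    I: float  # mU/L
    x1: float
    x2: float
    x3: float
    gut: float = 0.0  # mmol
    t: float = 0.0  # min

    def as_vector(self) -> np.ndarray:
        return np.array([self.Q1, self.Q2, self.I, self.x1, self.x2, self.x3, self.gut])

    @classmethod
    def from_vector(cls, y: Sequence[float], t: float) -> "PatientState":
        return cls(*(float(v) for v in y), t=float(t))

    def glucose(self, params: PatientParams) -> float:
        return self.Q1 / (params.V_G * params.weight)


@dataclass(frozen=True)
class ExogenousInput:
    """One minute's worth of exogenous drivers."""

    insulin_rate: float = 0.0  # U/h
    dextrose_rate: float = 0.0  # mL/h of 20% solution
    enteral_CHO: float = 0.0  # g/h

    def __post_init__(self) -> None:
        if self.insulin_rate < 0 or self.dextrose_rate < 0 or self.enteral_CHO < 0:
            raise ValueError("exogenous inputs must be non-negative")
        if self.insulin_rate > 50.0:
            raise ValueError("insulin_rate exceeds the 50 U/h delivery cap")
        if self.dextrose_rate > 200.0:
            raise ValueError("dextrose_rate exceeds the 200 mL/h delivery cap")


#: Nominal (population) parameter values. Volumes/rates follow the standard
#: two-compartment literature values; insulin sensitivities are scaled down to
#: reflect critical-illness insulin resistance. Implementation-chosen.
NOMINAL: dict[str, float] = {
    "V_G": 0.16,
    "k12": 0.066,
    "F01": 0.0097,
    "EGP0": 0.0161,
    "V_I": 0.12,
    "k_e": 0.138,
    "k_a1": 0.006,
    "k_a2": 0.06,
    "k_a3": 0.03,
    "S_IT": 1.8e-3,
    "S_ID": 2.9e-4,
    "S_IE": 1.8e-2,
    "gut_tau": 40.0,
}


def nominal_params(weight: float = 80.0, **overrides) -> PatientParams:
    """A population-nominal patient (used e.g. as the controller's internal model)."""
    kw = dict(NOMINAL)
    kw.update(overrides)
    return PatientParams(weight=weight, **kw)


# ---------------------------------------------------------------------------
# dynamics


def _rhs(y: np.ndarray, t: float, p: PatientParams, u_mU_min: float,
         dex_mmol_min: float, cho_mmol_min: float, extra_flux: float = 0.0) -> np.ndarray:
    """Time derivative of the 7-vector [Q1, Q2, I, x1, x2, x3, gut]."""
    Q1, Q2, I, x1, x2, x3, gut = y
    w = p.weight
    R = p.resistance_profile(t)
    gut_out = gut / p.gut_tau
    egp = p.EGP0 * w * max(0.0, 1.0 - x3)
    dQ1 = -p.F01 * w - x1 * Q1 + p.k12 * Q2 + egp + gut_out + dex_mmol_min + extra_flux
    dQ2 = x1 * Q1 - (p.k12 + x2) * Q2
    dI = u_mU_min / (p.V_I * w) - p.k_e * I
    IR = I * R
    dx1 = -p.k_a1 * x1 + p.k_a1 * p.S_IT * IR
    dx2 = -p.k_a2 * x2 + p.k_a2 * p.S_ID * IR
    dx3 = -p.k_a3 * x3 + p.k_a3 * p.S_IE * IR
    dgut = cho_mmol_min - gut_out
    return np.array([dQ1, dQ2, dI, dx1, dx2, dx3, dgut])


def derivatives(state: PatientState, params: PatientParams,
                inp: ExogenousInput) -> PatientState:
    """State derivative (per minute) under the given exogenous input.

    Unit conversions: insulin U/h -> mU/min; dextrose mL/h of 20% solution
    -> mmol/min; enteral CHO g/h -> mmol/min (1 g glucose = 5.551 mmol).
    """
    y = state.as_vector()
    if not np.all(np.isfinite(y)):
        raise DegenerateStateError("non-finite patient state")
    dy = _rhs(
        y,
        state.t,
        params,
        u_mU_min=inp.insulin_rate * 1000.0 / 60.0,
        dex_mmol_min=inp.dextrose_rate * DEXTROSE_G_PER_ML * MMOL_PER_G / 60.0,
        cho_mmol_min=inp.enteral_CHO * MMOL_PER_G / 60.0,
    )
    return PatientState.from_vector(dy, t=state.t)


def step(state: PatientState, params: PatientParams, inp: ExogenousInput,
         dt: float = 1.0) -> PatientState:
    """Advance the patient by ``dt`` minutes with one 4th-order Runge-Kutta step.

    Negative components (possible at coarse steps near zero) are clipped to 0
    with a logged warning.
    """
    if dt <= 0 or dt > 5.0:
        raise ValueError("dt must lie in (0, 5] minutes")
    y = state.as_vector()
    if not np.all(np.isfinite(y)):
        raise DegenerateStateError("non-finite patient state")
    args = (
        params,
        inp.insulin_rate * 1000.0 / 60.0,
        inp.dextrose_rate * DEXTROSE_G_PER_ML * MMOL_PER_G / 60.0,
        inp.enteral_CHO * MMOL_PER_G / 60.0,
    )
    t = state.t
    k1 = _rhs(y, t, *args)
    k2 = _rhs(y + 0.5 * dt * k1, t + 0.5 * dt, *args)
    k3 = _rhs(y + 0.5 * dt * k2, t + 0.5 * dt, *args)
    k4 = _rhs(y + dt * k3, t + dt, *args)
    y_new = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    if np.any(y_new < 0):
        logger.warning("clipping negative state components at t=%.1f min", t + dt)
        y_new = np.clip(y_new, 0.0, None)
    return PatientState.from_vector(y_new, t=t + dt)


# ---------------------------------------------------------------------------
# closed-form equilibrium


def _steady_glucose_or_limit(params: PatientParams, insulin_rate: float,
                             CHO: float, resistance: float) -> float:
    """Steady glucose, or +inf / 0.0 when the balance escapes up / down."""
    w = params.weight
    u_mU_min = insulin_rate * 1000.0 / 60.0
    I = u_mU_min / (params.V_I * w * params.k_e)
    IR = I * resistance
    x1 = params.S_IT * IR
    x2 = params.S_ID * IR
    x3 = params.S_IE * IR
    appearance = CHO * MMOL_PER_G / 60.0
    net = params.EGP0 * w * max(0.0, 1.0 - x3) + appearance - params.F01 * w
    if x1 <= 0.0 or x2 <= 0.0:
        # insulin exerts no glucose-lowering action
        return math.inf if net > 0 else (0.0 if net < 0 else math.nan)
    denom = x1 * x2 / (params.k12 + x2)
    if net <= 0.0:
        return 0.0
    Q1 = net / denom
    return Q1 / (params.V_G * w)


def steady_state_glucose(params: PatientParams, insulin_rate: float,
                         CHO: float = 0.0, resistance: float = 1.0) -> float:
    """Closed-form equilibrium plasma glucose (mM) under constant inputs.

    Raises :class:`NoEquilibriumError` when no finite positive equilibrium
    exists (e.g. zero insulin action with net positive glucose balance).
    """
    if insulin_rate < 0:
        raise ValueError("insulin_rate must be non-negative")
    g = _steady_glucose_or_limit(params, insulin_rate, CHO, resistance)
    if not math.isfinite(g) or g <= 0.0:
        raise NoEquilibriumError(
            f"no positive equilibrium at insulin {insulin_rate} U/h, CHO {CHO} g/h"
        )
    return g


def steady_state(params: PatientParams, insulin_rate: float, CHO: float = 0.0,
                 resistance: float = 1.0, t: float = 0.0) -> PatientState:
    """Full equilibrium state corresponding to :func:`steady_state_glucose`."""
    g = steady_state_glucose(params, insulin_rate, CHO, resistance)
    w = params.weight
    I = insulin_rate * 1000.0 / 60.0 / (params.V_I * w * params.k_e)
    IR = I * resistance
    x1, x2, x3 = params.S_IT * IR, params.S_ID * IR, params.S_IE * IR
    Q1 = g * params.V_G * w
    Q2 = x1 * Q1 / (params.k12 + x2)
    gut = CHO * MMOL_PER_G / 60.0 * params.gut_tau
    return PatientState(Q1=Q1, Q2=Q2, I=I, x1=x1, x2=x2, x3=x3, gut=gut, t=t)


def basal_for_glucose(params: PatientParams, G_target: float, CHO: float = 0.0,
                      resistance: float = 1.0, u_max: float = 50.0) -> float:
    """Invert the equilibrium: constant insulin rate (U/h) holding ``G_target``.

    Steady glucose is strictly decreasing in the insulin rate wherever an
    equilibrium exists, so plain bisection applies.
    """

    def g(u: float) -> float:
        v = _steady_glucose_or_limit(params, u, CHO, resistance)
        return v if not math.isnan(v) else G_target

    lo, hi = 1e-4, u_max
    if g(hi) > G_target:
        raise NoEquilibriumError(f"cannot reach {G_target} mM below {u_max} U/h")
    if g(lo) < G_target:
        raise NoEquilibriumError(f"glucose below {G_target} mM even at ~0 insulin")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if g(mid) > G_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class CohortConfig:
    """Sampling distributions for virtual-subject generation.

    Entry glucose and basal-rate ranges emulate a hyperglycemic ICU cohort
    (~10-11 mM at entry, ~46% with known diabetes); per-subject insulin
    sensitivity is solved so the sampled basal rate actually maintains the
    sampled entry glucose at the reference carbohydrate intake.
    """

    diabetes_p: float = 0.46
    weight_median: float = 80.0
    weight_sigma: float = 0.18  # lognormal sigma
    weight_bounds: tuple = (45.0, 180.0)
    bmi_mean: float = 28.0
    bmi_sd: float = 4.0
    apache_mean: float = 12.0
    apache_sd: float = 4.0
    g_base_mean: float = 10.8
    g_base_sd: float = 1.5
    g_base_bounds: tuple = (8.2, 13.8)
    u_base_range: tuple = (1.5, 4.0)
    cho_ref: float = 7.5  # g/h carbohydrate used when anchoring sensitivity
    param_cv: float = 0.15  # lognormal CV for rate/volume jitter
    sens_cv: float = 0.2  # extra lognormal jitter on sensitivities
    resistance_amp_range: tuple = (0.05, 0.35)
    resistance_period_range: tuple = (240.0, 720.0)


def _lognormal(rng: np.random.Generator, nominal: float, cv: float) -> float:
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(nominal * rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def make_cohort(n: int, seed, config: CohortConfig | None = None) -> list[PatientParams]:
    """Sample ``n`` virtual subjects reproducibly from ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = config or CohortConfig()
    if not (0.0 <= cfg.diabetes_p <= 1.0):
        raise ValueError("diabetes_p must be a probability")
    if cfg.u_base_range[0] <= 0 or cfg.u_base_range[1] > 50:
        raise ValueError("u_base_range outside (0, 50]")
    rng = np.random.default_rng(seed)
    cohort: list[PatientParams] = []
    for i in range(n):
        weight = float(np.clip(cfg.weight_median * rng.lognormal(0.0, cfg.weight_sigma),
                               *cfg.weight_bounds))
        jitter = {k: _lognormal(rng, v, cfg.param_cv)
                  for k, v in NOMINAL.items()
                  if k not in ("S_IT", "S_ID", "S_IE", "gut_tau")}
        sens = {k: _lognormal(rng, NOMINAL[k], cfg.sens_cv)
                for k in ("S_IT", "S_ID", "S_IE")}
        profile = SinusoidResistance(
            amplitude=float(rng.uniform(*cfg.resistance_amp_range)),
            period_min=float(rng.uniform(*cfg.resistance_period_range)),
            phase=float(rng.uniform(0.0, 2.0 * math.pi)),
        )
        g_base = float(np.clip(rng.normal(cfg.g_base_mean, cfg.g_base_sd),
                               *cfg.g_base_bounds))
        u_base = float(rng.uniform(*cfg.u_base_range))
        diabetes = bool(rng.random() < cfg.diabetes_p)
        bmi = float(np.clip(rng.normal(cfg.bmi_mean, cfg.bmi_sd), 17.0, 45.0))
        apache = float(np.clip(round(rng.normal(cfg.apache_mean, cfg.apache_sd)), 0, 40))

        p = PatientParams(weight=weight, gut_tau=NOMINAL["gut_tau"],
                          resistance_profile=profile, diabetes=diabetes,
                          apache2=apache, bmi=bmi, basal_insulin=u_base,
                          baseline_glucose=g_base, subject_id=i,
                          **jitter, **sens)
        scale = _solve_sensitivity_scale(p, u_base, g_base, cfg.cho_ref)
        p = replace(p, S_IT=p.S_IT * scale, S_ID=p.S_ID * scale, S_IE=p.S_IE * scale)
        cohort.append(p)
    return cohort


def _solve_sensitivity_scale(p: PatientParams, u_base: float, g_base: float,
                             cho: float) -> float:
    """Common multiplier on (S_IT, S_ID, S_IE) so steady G(u_base) = g_base."""

    def g_of(scale: float) -> float:
        q = replace(p, S_IT=p.S_IT * scale, S_ID=p.S_ID * scale, S_IE=p.S_IE * scale)
        v = _steady_glucose_or_limit(q, u_base, cho, 1.0)
        return v if not math.isnan(v) else math.inf

    lo, hi = 1e-3, 1e3
    # g_of is decreasing in scale; widen bracket defensively
    for _ in range(90):
        mid = math.sqrt(lo * hi)
        if g_of(mid) > g_base:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


# ---------------------------------------------------------------------------
# trajectory export


def trajectory_frame(times, states, params, inputs):
    """Assemble a trajectory table (t_min, G_mM, I_mUL, insulin_Uh, dextrose_mLh, CHO_gh)."""
    import pandas as pd

    return pd.DataFrame({
        "t_min": list(times),
        "G_mM": [s.glucose(params) for s in states],
        "I_mUL": [s.I for s in states],
        "insulin_Uh": [u.insulin_rate for u in inputs],
        "dextrose_mLh": [u.dextrose_rate for u in inputs],
        "CHO_gh": [u.enteral_CHO for u in inputs],
    })
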