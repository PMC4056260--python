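"""Adaptive model-predictive insulin/dextrose controller.

Every 5 minutes the controller assimilates the latest sensor glucose (or,
when the sensor is unavailable, the latest arterial reference value held
between hourly samples), adapts two parameters — a fast additive glucose-flux
correction ``F_c`` and a slow estimate ``b_est`` of the insulin rate that
maintains euglycemia — and then either

* minimises a quadratic cost of predicted glucose deviation from the setpoint
  over a 90-minute horizon on a 0.05-U/h insulin grid, or
* when the predicted 40-minute glucose minimum falls below a rescue
  threshold, commands 20% dextrose instead.

Safety rules cap insulin at 50 U/h and dextrose at 200 mL/h, forbid
simultaneous insulin and dextrose, and suspend insulin whenever observed
glucose drops more than 1.2 mM below the setpoint.

The internal model is the population compartment model at the patient's
weight. ``b_est`` enters as an insulin-input offset: the model is driven with
``u - b_est + b_ref`` where ``b_ref`` is the population model's own
closed-form requirement at the setpoint, so the model predicts a flat
trajectory at ``u = b_est`` once adapted — which makes ``b_est`` converge to
the patient's true steady requirement under constant conditions.

The controller receives no information about enteral or parenteral
nutrition; unmodelled glucose appearance is absorbed by ``F_c``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .patient import (
    PatientParams,
    basal_for_glucose,
    nominal_params,
    steady_state,
)

__all__ = [
    "ControllerConfig",
    "ControllerState",
    "DoseCommand",
    "OffGridError",
    "initialize",
    "assimilate",
    "predict",
    "compute_insulin",
    "compute_dextrose",
    "is_insulin_suspended",
    "schedule_calibration",
    "note_reference",
    "control_cycle",
    "replay",
]

INSULIN_CAP = 50.0  # U/h
DEXTROSE_CAP = 200.0  # mL/h


class OffGridError(ValueError):
    """Control cycles must be called on the 5-minute grid."""


@dataclass
class ControllerConfig:
    G_target: float = 7.0  # mM, midpoint of the 6.0-8.0 mM target band
    suspend_offset: float = 1.2  # mM below target at which insulin is suspended
    cycle_min: float = 5.0
    horizon_insulin: float = 90.0  # min (printed range 60-90)
    horizon_dextrose: float = 40.0  # min (printed range 30-40)
    pred_dt: float = 5.0
    grid_step: float = 0.05  # U/h
    G_rescue: float = 4.5  # mM, predicted-minimum threshold for dextrose
    K_d: float = 300.0  # mL/h of 20% dextrose per mM of predicted shortfall
    # cost: lambda_u such that a 1 U/h move costs as much as a sustained
    # 0.3 mM offset over the 18-point insulin horizon
    lambda_u: float = 18 * 0.3 ** 2
    # assimilation gains
    alpha_state: float = 0.7  # fraction of the innovation applied to Q1
    tau_f: float = 30.0  # min, decay time constant of F_c
    K_f: float = 0.30  # mmol/min of F_c per mM of innovation, per cycle
    K_b: float = 0.010  # U/h of b_est per (mM * min) of integrated innovation
    b_est_prior_per_kg: float = 0.02  # U/kg/h initialisation
    # calibration scheduling
    cal_low_glucose: float = 3.5  # mM
    cal_low_interval: float = 30.0  # min
    cal_dev_lo: float = 0.02  # relative deviation mapped to the longest interval
    cal_dev_hi: float = 0.20  # relative deviation mapped to the shortest interval
    cal_interval_min: float = 60.0
    cal_interval_max: float = 360.0


@dataclass
class ControllerState:
    params: PatientParams  # population model at the patient's weight
    model_y: np.ndarray  # internal [Q1, Q2, I, x1, x2, x3]
    b_ref: float  # U/h, population-model requirement at the setpoint
    F_c: float = 0.0  # mmol/min
    b_est: float = 0.0  # U/h
    u_prev: float = 0.0  # U/h
    G_target: float = 7.0
    next_cal_due: float = 60.0  # min
    mode: str = "fallback"  # "sensor" | "fallback"
    last_obs: float = float("nan")
    last_reference: float = float("nan")
    t: float = 0.0
    config: ControllerConfig = field(default_factory=ControllerConfig)

    @property
    def model_glucose(self) -> float:
        return float(self.model_y[0]) / (self.params.V_G * self.params.weight)


# ---------------------------------------------------------------------------
# internal model dynamics (vectorised over candidate insulin rates)


def _model_rhs(Y: np.ndarray, p: PatientParams, dI_in: np.ndarray,
               F_c: float) -> np.ndarray:
    """RHS for a batch of internal-model states, layout (6, N).

    ``dI_in`` is the precomputed plasma-insulin inflow u/(V_I w) in
    mU/L/min (one entry per candidate insulin rate).
    """
    Q1, Q2, I, x1, x2, x3 = Y
    w = p.weight
    out = np.empty_like(Y)
    egp = 1.0 - x3
    np.maximum(egp, 0.0, out=egp)
    out[0] = -p.F01 * w + p.EGP0 * w * egp - x1 * Q1 + p.k12 * Q2 + F_c
    out[1] = x1 * Q1 - (p.k12 + x2) * Q2
    out[2] = dI_in - p.k_e * I
    out[3] = p.k_a1 * (p.S_IT * I - x1)
    out[4] = p.k_a2 * (p.S_ID * I - x2)
    out[5] = p.k_a3 * (p.S_IE * I - x3)
    return out


def _advance(Y: np.ndarray, p: PatientParams, u_mU_min: np.ndarray, F_c: float,
             dt: float, steps: int):
    """RK4-advance a batch of internal-model states, layout (6, N).

    Returns ``(G, Y)`` with predicted glucose of shape (N, steps).
    """
    G = np.empty((Y.shape[1], steps))
    vw = p.V_G * p.weight
    dI_in = u_mU_min / (p.V_I * p.weight)
    for k in range(steps):
        k1 = _model_rhs(Y, p, dI_in, F_c)
        k2 = _model_rhs(Y + 0.5 * dt * k1, p, dI_in, F_c)
        k3 = _model_rhs(Y + 0.5 * dt * k2, p, dI_in, F_c)
        k4 = _model_rhs(Y + dt * k3, p, dI_in, F_c)
        Y = Y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        np.clip(Y, 0.0, None, out=Y)
        G[:, k] = Y[0] / vw
    return G, Y


def _u_effective(cs: ControllerState, u) -> np.ndarray:
    """Model insulin input in mU/min for commanded rate(s) ``u`` in U/h."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    return np.maximum(0.0, u - cs.b_est + cs.b_ref) * 1000.0 / 60.0


# ---------------------------------------------------------------------------
# operations


def initialize(weight: float, reference_G: float, G_target: float = 7.0,
               config: ControllerConfig | None = None) -> ControllerState:
    """Set up the controller from the patient's weight and one reference value.

    The internal model starts at the equilibrium consistent with the
    reference glucose; ``b_est`` starts from a weight-based prior
    (0.02 U/kg/h).
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    if not (1.0 <= reference_G <= 40.0):
        raise ValueError("reference_G outside [1, 40] mM")
    cfg = config or ControllerConfig()
    pop = nominal_params(weight=weight)
    b_ref = basal_for_glucose(pop, G_target)
    u_eq = basal_for_glucose(pop, reference_G)
    st = steady_state(pop, u_eq)
    model_y = st.as_vector()[:6]
    return ControllerState(params=pop, model_y=model_y, b_ref=b_ref,
                           b_est=cfg.b_est_prior_per_kg * weight,
                           G_target=G_target, next_cal_due=60.0,
                           last_obs=reference_G, last_reference=reference_G,
                           config=cfg)


def assimilate(cs: ControllerState, G_obs: float, basis: str = "sensor",
               dt: float = 5.0) -> ControllerState:
    """Advance the internal model and absorb the innovation.

    e = G_obs - Ghat updates, in order: a direct state nudge on Q1 (so
    predictions start near the measurement), the fast flux correction
    ``F_c <- lambda_f F_c + K_f e`` and the slow basal estimate
    ``b_est <- clamp(b_est + K_b e dt, 0, 50)``.
    """
    if not (G_obs > 0 and math.isfinite(G_obs)):
        raise ValueError("G_obs must be positive and finite")
    cfg = cs.config
    u_eff = _u_effective(cs, cs.u_prev)
    _, Y = _advance(cs.model_y[:, None].copy(), cs.params, u_eff, cs.F_c,
                    dt=dt, steps=1)
    cs.model_y = Y[:, 0]
    e = G_obs - cs.model_glucose
    if not math.isfinite(e):
        raise ValueError("non-finite innovation")
    vw = cs.params.V_G * cs.params.weight
    cs.model_y[0] = max(0.0, cs.model_y[0] + cfg.alpha_state * e * vw)
    lam_f = math.exp(-dt / cfg.tau_f)
    cs.F_c = lam_f * cs.F_c + cfg.K_f * e
    cs.b_est = float(np.clip(cs.b_est + cfg.K_b * e * dt, 0.0, INSULIN_CAP))
    cs.last_obs = G_obs
    cs.mode = basis
    cs.t += dt
    return cs


def predict(cs: ControllerState, u: float, horizon: float | None = None) -> np.ndarray:
    """Forward-simulate the internal model at constant insulin rate ``u``.

    Returns predicted glucose on the 5-minute grid (excluding t0). The model
    carries the current ``F_c`` and ``b_est`` context and — like the clinical
    system — knows nothing about nutrition.
    """
    cfg = cs.config
    if horizon is None:
        horizon = cfg.horizon_insulin
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if u < 0:
        raise ValueError("insulin rate must be non-negative")
    steps = max(1, int(round(horizon / cfg.pred_dt)))
    G, _ = _advance(cs.model_y[:, None].copy(), cs.params, _u_effective(cs, u),
                    cs.F_c, dt=cfg.pred_dt, steps=steps)
    return G[0]


def is_insulin_suspended(cs: ControllerState, G_obs: float | None = None) -> bool:
    """Low-glucose suspend: no insulin below ``G_target - suspend_offset``."""
    g = cs.last_obs if G_obs is None else G_obs
    return g < cs.G_target - cs.config.suspend_offset


def compute_insulin(cs: ControllerState, grid_step: float | None = None) -> float:
    """Insulin rate minimising the predicted-deviation cost, after safety rules.

    J(u) = sum_k (Ghat_k(u) - G_target)^2 + lambda_u (u - u_prev)^2 over the
    insulin horizon, minimised on the {0, 0.05, ..., 50} U/h grid.
    """
    cfg = cs.config
    if is_insulin_suspended(cs):
        return 0.0
    step = grid_step or cfg.grid_step
    grid = np.arange(0.0, INSULIN_CAP + 0.5 * step, step)
    grid[-1] = min(grid[-1], INSULIN_CAP)
    steps = int(round(cfg.horizon_insulin / cfg.pred_dt))
    Y0 = np.repeat(cs.model_y[:, None], grid.size, axis=1)
    G, _ = _advance(Y0, cs.params, _u_effective(cs, grid), cs.F_c,
                    dt=cfg.pred_dt, steps=steps)
    J = ((G - cs.G_target) ** 2).sum(axis=1) + cfg.lambda_u * (grid - cs.u_prev) ** 2
    return float(grid[int(np.argmin(J))])


def compute_dextrose(cs: ControllerState) -> float:
    """20% dextrose rate when the insulin-free 40-minute forecast dips low.

    If the predicted minimum falls below ``G_rescue``, dose proportionally to
    the shortfall (``K_d`` mL/h per mM), capped at 200 mL/h.
    """
    cfg = cs.config
    g_min = float(np.min(predict(cs, 0.0, cfg.horizon_dextrose)))
    if g_min >= cfg.G_rescue:
        return 0.0
    return float(min(DEXTROSE_CAP, cfg.K_d * (cfg.G_rescue - g_min)))


def schedule_calibration(cs: ControllerState, sensor_G: float,
                         last_deviation: float) -> float:
    """Minutes until the next reference-glucose request.

    Below 3.5 mM sensor glucose the request comes every 30 minutes;
    otherwise the interval maps linearly from the sensor/reference relative
    deviation: <=2% -> 6 h, >=20% -> 1 h.
    """
    cfg = cs.config
    if last_deviation < 0:
        raise ValueError("deviation must be non-negative")
    if sensor_G < cfg.cal_low_glucose:
        return cfg.cal_low_interval
    d = float(np.clip(last_deviation, cfg.cal_dev_lo, cfg.cal_dev_hi))
    frac = (cfg.cal_dev_hi - d) / (cfg.cal_dev_hi - cfg.cal_dev_lo)
    return float(np.clip(cfg.cal_interval_min
                         + (cfg.cal_interval_max - cfg.cal_interval_min) * frac,
                         cfg.cal_interval_min, cfg.cal_interval_max))


def note_reference(cs: ControllerState, reference_G: float) -> None:
    """Record an arterial reference value (fallback dosing carries it forward)."""
    if not (1.0 <= reference_G <= 40.0):
        raise ValueError("reference_G outside [1, 40] mM")
    cs.last_reference = reference_G


@dataclass(frozen=True)
class DoseCommand:
    """One 5-minute dosing decision, after all safety clamps."""

    t: float  # min
    insulin: float  # U/h
    dextrose: float  # mL/h of 20% solution
    basis: str  # "sensor" | "reference-fallback"

    def __post_init__(self) -> None:
        if not (0.0 <= self.insulin <= INSULIN_CAP):
            raise ValueError("insulin outside [0, 50] U/h")
        if not (0.0 <= self.dextrose <= DEXTROSE_CAP):
            raise ValueError("dextrose outside [0, 200] mL/h")
        if self.insulin > 0 and self.dextrose > 0:
            raise ValueError("insulin and dextrose must not run simultaneously")


def control_cycle(cs: ControllerState, t: float,
                  sensor_reading: float | None,
                  reference: float | None = None) -> tuple[ControllerState, DoseCommand]:
    """One 5-minute decision: assimilate, then dose insulin or dextrose.

    ``sensor_reading=None`` means the CGM is warming up or dropped out; the
    controller then runs on the latest reference value (zero-order hold) and
    flags the command as reference-fallback.
    """
    if t % 5 != 0:
        raise OffGridError(f"control cycle called off the 5-min grid (t={t})")
    if reference is not None:
        note_reference(cs, reference)
    if sensor_reading is not None:
        basis, G_obs = "sensor", sensor_reading
    else:
        basis, G_obs = "reference-fallback", cs.last_reference
        if not math.isfinite(G_obs):
            raise ValueError("fallback requested but no reference value known")
    assimilate(cs, G_obs, basis=basis, dt=cs.config.cycle_min)
    dextrose = compute_dextrose(cs)
    insulin = 0.0 if dextrose > 0 else compute_insulin(cs)
    cs.u_prev = insulin
    return cs, DoseCommand(t=t, insulin=insulin, dextrose=dextrose, basis=basis)


# ---------------------------------------------------------------------------
# replay


def replay(frame, weight: float, G_target: float = 7.0,
           config: ControllerConfig | None = None):
    """Re-run the controller over a logged (t, sensor, reference) time series.

    ``frame`` must have columns ``t_min``, ``sensor_mM`` (NaN when
    unavailable) and ``reference_mM`` (NaN except when a reference sample was
    drawn). Returns the deterministic command log as a DataFrame.
    """
    import pandas as pd

    frame = frame.sort_values("t_min").reset_index(drop=True)
    refs = frame.dropna(subset=["reference_mM"])
    if refs.empty:
        raise ValueError("replay needs at least one reference value")
    cs = initialize(weight, float(refs.iloc[0]["reference_mM"]), G_target, config)
    rows = []
    for _, row in frame.iterrows():
        t = float(row["t_min"])
        ref = None if pd.isna(row["reference_mM"]) else float(row["reference_mM"])
        if ref is not None:
            note_reference(cs, ref)
        if t % 5 != 0:
            continue
        reading = None if pd.isna(row["sensor_mM"]) else float(row["sensor_mM"])
        cs, cmd = control_cycle(cs, t, reading)
        rows.append({"t_min": t, "basis": cmd.basis, "insulin_Uh": cmd.insulin,
                     "dextrose_mLh": cmd.dextrose, "internal_G_mM": cs.model_glucose,
                     "F_c": cs.F_c, "b_est": cs.b_est,
                     "next_cal_due": cs.next_cal_due})
    return pd.DataFrame(rows)
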