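"""In-silico randomized trial: minimization randomization, per-subject 48-h
simulation of either treatment arm, and full trace logging.

Each virtual subject is simulated at 1-minute physiology steps with enteral
feeding (including interruptions), an optional steroid episode raising
insulin resistance, hourly arterial reference samples, and either

* the closed-loop arm: a CGM read every minute, the adaptive MPC deciding
  insulin or dextrose every 5 minutes, calibration requests honoured as the
  controller schedules them; or
* the comparator arm: the intravenous sliding scale applied to the hourly
  reference value by a virtual nurse, held between samples.

The whole trial is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import controller as ctrl
from . import sensor as sns
from .patient import (
    ArrayResistance,
    basal_for_glucose,
    CohortConfig,
    ExogenousInput,
    PatientParams,
    ProductResistance,
    make_cohort,
    steady_state,
    step,
)
from .sliding_scale import NurseProtocol
from .stats import summarize

__all__ = [
    "SubjectCovariates",
    "TrialRecord",
    "ScenarioConfig",
    "Scenario",
    "TrialConfig",
    "minimization_assign",
    "make_scenario",
    "simulate_subject",
    "run_trial",
]

CL_ARM = "closed-loop"
SS_ARM = "sliding-scale"


@dataclass(frozen=True)
class SubjectCovariates:
    """Balancing covariates for minimization randomization."""

    apache2: float
    G_rand: float  # mM, glucose at randomization
    bmi: float
    diabetes: bool

    def __post_init__(self) -> None:
        if not (math.isfinite(self.apache2) and math.isfinite(self.G_rand)
                and math.isfinite(self.bmi)):
            raise ValueError("covariates must be finite")
        if self.apache2 < 0 or self.G_rand <= 0:
            raise ValueError("invalid covariates")


#: Category cut-points, near the cohort medians of the emulated population.
DEFAULT_CUTS = {"apache2": 12.0, "G_rand": 10.0, "bmi": 28.0}


def _levels(c: SubjectCovariates, cuts: dict) -> tuple:
    return (c.apache2 > cuts["apache2"], c.G_rand > cuts["G_rand"],
            c.bmi > cuts["bmi"], bool(c.diabetes))


def minimization_assign(new: SubjectCovariates, groupA, groupB,
                        rng: np.random.Generator,
                        cuts: dict | None = None) -> str:
    """Taves-style minimization over the four balancing factors.

    For each factor, subjects sharing the new subject's category level are
    counted per arm; the total imbalance sum |countA - countB| is evaluated
    after hypothetically assigning the new subject to each arm, and the arm
    with the smaller total wins. Exact ties are broken by a fair coin.
    """
    cuts = cuts or DEFAULT_CUTS
    lv = _levels(new, cuts)
    nA = [sum(1 for c in groupA if _levels(c, cuts)[f] == lv[f]) for f in range(4)]
    nB = [sum(1 for c in groupB if _levels(c, cuts)[f] == lv[f]) for f in range(4)]
    score_A = sum(abs((nA[f] + 1) - nB[f]) for f in range(4))
    score_B = sum(abs(nA[f] - (nB[f] + 1)) for f in range(4))
    if score_A < score_B:
        return "A"
    if score_B < score_A:
        return "B"
    return "A" if rng.random() < 0.5 else "B"


# ---------------------------------------------------------------------------
# scenarios


@dataclass
class ScenarioConfig:
    """Feeding and concomitant-treatment emulation (per-subject)."""

    cho_mean: float = 7.5  # g/h
    cho_sd: float = 2.0
    max_interruptions_per_day: int = 2
    interruption_duration_range: tuple = (60.0, 180.0)  # min
    steroid_prob: float = 0.33
    steroid_factor: float = 1.5
    steroid_duration: float = 720.0  # min


@dataclass
class Scenario:
    cho: np.ndarray  # g/h per minute
    resistance_extra: np.ndarray  # multiplicative factor per minute
    cho_base: float
    interruptions: tuple
    steroid_window: tuple | None


def make_scenario(seed, config: ScenarioConfig | None = None,
                  duration_min: float = 2880.0) -> Scenario:
    """Draw one subject's nutrition schedule and resistance episodes."""
    cfg = config or ScenarioConfig()
    rng = np.random.default_rng(seed)
    n = int(duration_min) + 1
    cho_base = max(0.0, float(rng.normal(cfg.cho_mean, cfg.cho_sd)))
    cho = np.full(n, cho_base)
    interruptions = []
    n_days = max(1, int(round(duration_min / 1440.0)))
    for day in range(n_days):
        k = int(rng.integers(0, cfg.max_interruptions_per_day + 1))
        for _ in range(k):
            start = float(rng.uniform(day * 1440.0, (day + 1) * 1440.0))
            dur = float(rng.uniform(*cfg.interruption_duration_range))
            a, b = int(start), min(n, int(start + dur))
            cho[a:b] = 0.0
            interruptions.append((start, start + dur))
    extra = np.ones(n)
    steroid_window = None
    if rng.random() < cfg.steroid_prob:
        start = float(rng.uniform(0.0, max(1.0, duration_min - cfg.steroid_duration)))
        a, b = int(start), min(n, int(start + cfg.steroid_duration))
        extra[a:b] = cfg.steroid_factor
        steroid_window = (start, start + cfg.steroid_duration)
    return Scenario(cho=cho, resistance_extra=extra, cho_base=cho_base,
                    interruptions=tuple(interruptions),
                    steroid_window=steroid_window)


# ---------------------------------------------------------------------------
# per-subject simulation


@dataclass
class TrialRecord:
    subject_id: int
    arm: str
    reference: pd.DataFrame  # hourly (t_min, G_mM)
    sensor: pd.DataFrame | None  # per-minute (t_min, sensor_mM, available, cal_event)
    commands: pd.DataFrame  # ZOH dose log
    calibrations: pd.DataFrame | None  # algorithm-requested reference draws
    nutrition: pd.DataFrame  # change points of the CHO schedule
    duration_h: float

    def __post_init__(self) -> None:
        if self.duration_h > 48.0:
            raise ValueError("duration exceeds the 48-h study maximum")
        t = self.reference["t_min"].to_numpy(float)
        if t.size >= 2 and not np.all(np.diff(t) == 60.0):
            raise ValueError("reference cadence must be exactly hourly")


def _nutrition_frame(cho: np.ndarray) -> pd.DataFrame:
    idx = np.unique(np.concatenate([[0], np.flatnonzero(np.diff(cho) != 0) + 1]))
    return pd.DataFrame({"t_min": idx.astype(float), "CHO_gh": cho[idx]})


@dataclass
class TrialConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    sensor: sns.SensorConfig = field(default_factory=sns.SensorConfig)
    controller: ctrl.ControllerConfig = field(default_factory=ctrl.ControllerConfig)
    duration_h: float = 48.0
    G_target: float = 7.0
    nurse_escalation: bool = False
    g_rand_noise_sd: float = 0.3  # mM, measurement noise on the entry glucose


def simulate_subject(params: PatientParams, arm: str, scenario: Scenario,
                     seed, config: TrialConfig | None = None) -> TrialRecord:
    """Simulate one subject for up to 48 h under the given arm's policy."""
    cfg = config or TrialConfig()
    if cfg.duration_h > 48.0:
        raise ValueError("duration_h must be <= 48")
    duration_min = int(round(cfg.duration_h * 60.0))
    if scenario.cho.size < duration_min + 1:
        raise ValueError("scenario shorter than the requested duration")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_sensor, rng_ref = (np.random.default_rng(s) for s in ss.spawn(2))

    p_run = replace(params, resistance_profile=ProductResistance(
        (params.resistance_profile, ArrayResistance(tuple(scenario.resistance_extra)))))
    # admission state: the insulin drip that holds the subject's entry glucose
    # at the scenario's feed rate (subjects enter hyperglycemic, most already
    # on an insulin infusion)
    u0 = basal_for_glucose(p_run, params.baseline_glucose, CHO=scenario.cho_base)
    state = steady_state(p_run, u0, CHO=scenario.cho_base)

    refs: list[tuple[float, float]] = []
    if arm == CL_ARM:
        rec = _run_closed_loop(p_run, state, scenario, duration_min, cfg,
                               rng_sensor, rng_ref, refs)
    elif arm == SS_ARM:
        rec = _run_sliding_scale(p_run, state, scenario, duration_min, cfg,
                                 rng_ref, refs)
    else:
        raise ValueError(f"unknown arm {arm!r}")
    sensor_df, commands, cal_df = rec
    return TrialRecord(
        subject_id=params.subject_id, arm=arm,
        reference=pd.DataFrame(refs, columns=["t_min", "G_mM"]),
        sensor=sensor_df, commands=commands, calibrations=cal_df,
        nutrition=_nutrition_frame(scenario.cho[:duration_min + 1]),
        duration_h=cfg.duration_h,
    )


def _run_closed_loop(p_run, state, scenario, duration_min, cfg,
                     rng_sensor, rng_ref, refs):
    sensor = sns.new_sensor(state.glucose(p_run), rng_sensor, cfg.sensor,
                            t_start=0.0, duration_min=duration_min)
    G0 = state.glucose(p_run)
    ref0 = sns.reference_sample(G0, rng_ref)
    refs.append((0.0, ref0))
    cs = ctrl.initialize(p_run.weight, ref0, cfg.G_target, cfg.controller)

    sensor_rows, cmd_rows, cal_rows = [], [], []
    u_cmd = dex_cmd = 0.0
    for t in range(duration_min + 1):
        G = state.glucose(p_run)
        cal_event = False
        if t > 0 and t % 60 == 0:
            ref = sns.reference_sample(G, rng_ref)
            refs.append((float(t), ref))
            ctrl.note_reference(cs, ref)
        if t < duration_min and t >= cs.next_cal_due:
            ref_c = sns.reference_sample(G, rng_ref)
            ctrl.note_reference(cs, ref_c)
            pre = sns.read(sensor, rng_sensor)
            if pre is not None:
                dev = abs(pre - ref_c) / ref_c
                sns.calibrate(sensor, ref_c, t)
                cs.next_cal_due = t + ctrl.schedule_calibration(cs, pre, dev)
                cal_event = True
                cal_rows.append({"t_min": float(t), "reference_mM": ref_c,
                                 "deviation": dev})
            else:
                # sensor down: fall back to hourly reference cadence
                cs.next_cal_due = t + 60.0
                cal_rows.append({"t_min": float(t), "reference_mM": ref_c,
                                 "deviation": float("nan")})
        disp = sns.read(sensor, rng_sensor)
        sensor_rows.append({"t_min": float(t),
                            "sensor_mM": float("nan") if disp is None else disp,
                            "available": sensor.available,
                            "cal_event": cal_event})
        if t % 5 == 0 and t < duration_min:
            cs, cmd = ctrl.control_cycle(cs, t, disp)
            cmd_rows.append({"t_min": float(t), "basis": cmd.basis,
                             "insulin_Uh": cmd.insulin,
                             "dextrose_mLh": cmd.dextrose,
                             "internal_G_mM": cs.model_glucose,
                             "F_c": cs.F_c, "b_est": cs.b_est,
                             "next_cal_due": cs.next_cal_due})
            u_cmd, dex_cmd = cmd.insulin, cmd.dextrose
        if t < duration_min:
            inp = ExogenousInput(insulin_rate=u_cmd, dextrose_rate=dex_cmd,
                                 enteral_CHO=float(scenario.cho[t]))
            sns.sensor_step(G, sensor, 1.0)
            state = step(state, p_run, inp, 1.0)
    return (pd.DataFrame(sensor_rows), pd.DataFrame(cmd_rows),
            pd.DataFrame(cal_rows, columns=["t_min", "reference_mM", "deviation"]))


def _run_sliding_scale(p_run, state, scenario, duration_min, cfg, rng_ref, refs):
    nurse = NurseProtocol(escalation=cfg.nurse_escalation)
    cmd_rows = []
    rate = 0.0
    for t in range(duration_min + 1):
        G = state.glucose(p_run)
        if t % 60 == 0:
            ref = sns.reference_sample(G, rng_ref)
            refs.append((float(t), ref))
            if t < duration_min:
                rate = nurse.hourly(float(t), ref)
                cmd_rows.append({"t_min": float(t), "basis": "sliding-scale",
                                 "insulin_Uh": rate, "dextrose_mLh": 0.0,
                                 "internal_G_mM": float("nan"),
                                 "F_c": float("nan"), "b_est": float("nan"),
                                 "next_cal_due": float("nan")})
        if t < duration_min:
            inp = ExogenousInput(insulin_rate=rate, dextrose_rate=0.0,
                                 enteral_CHO=float(scenario.cho[t]))
            state = step(state, p_run, inp, 1.0)
    return None, pd.DataFrame(cmd_rows), None


# ---------------------------------------------------------------------------
# full trial


def run_trial(n_per_arm: int, seed, config: TrialConfig | None = None):
    """Cohort -> minimization -> per-subject simulation -> outcome report.

    Subjects are enrolled sequentially and assigned by minimization until
    both arms hold ``n_per_arm``; once an arm is full the remainder go to the
    other. Returns ``(records, report)`` where ``report`` is the output of
    :func:`iculoop.stats.summarize` keyed by arm name.
    """
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be >= 1")
    cfg = config or TrialConfig()
    ss = np.random.SeedSequence(seed)
    s_cohort, s_assign, s_noise, s_subjects = ss.spawn(4)
    cohort = make_cohort(2 * n_per_arm, s_cohort, cfg.cohort)
    rng_assign = np.random.default_rng(s_assign)
    rng_noise = np.random.default_rng(s_noise)
    subject_seeds = s_subjects.spawn(2 * n_per_arm)

    groupA: list[SubjectCovariates] = []
    groupB: list[SubjectCovariates] = []
    records: list[TrialRecord] = []
    for i, params in enumerate(cohort):
        cov = SubjectCovariates(
            apache2=params.apache2,
            G_rand=params.baseline_glucose + float(rng_noise.normal(0, cfg.g_rand_noise_sd)),
            bmi=params.bmi, diabetes=params.diabetes,
        )
        if len(groupA) >= n_per_arm:
            side = "B"
        elif len(groupB) >= n_per_arm:
            side = "A"
        else:
            side = minimization_assign(cov, groupA, groupB, rng_assign)
        (groupA if side == "A" else groupB).append(cov)
        arm = CL_ARM if side == "A" else SS_ARM
        sub_ss = subject_seeds[i]
        s_scn, s_sim = sub_ss.spawn(2)
        scenario = make_scenario(s_scn, cfg.scenario,
                                 duration_min=cfg.duration_h * 60.0)
        records.append(simulate_subject(params, arm, scenario, s_sim, cfg))
    report = summarize({
        SS_ARM: [r for r in records if r.arm == SS_ARM],
        CL_ARM: [r for r in records if r.arm == CL_ARM],
    })
    return records, report
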