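"""MPC controller: initialization, two-parameter adaptation, prediction,
grid optimisation, safety rules and the 5-minute cycle contract."""

import math
from dataclasses import replace

import numpy as np
import pytest

from iculoop import controller as C
from iculoop.patient import (
    ConstantResistance,
    ExogenousInput,
    basal_for_glucose,
    make_cohort,
    steady_state,
    step,
)


def fresh(weight=80.0, ref=10.0, **cfg_kw):
    cfg = C.ControllerConfig(**cfg_kw)
    return C.initialize(weight, ref, config=cfg)


def model_prediction_next(cs):
    """One 5-min advance of a copy of the internal model (oracle for e=0)."""
    G, _ = C._advance(cs.model_y[:, None].copy(), cs.params,
                      C._u_effective(cs, cs.u_prev), cs.F_c, dt=5.0, steps=1)
    return float(G[0, -1])


class TestInitialize:
    def test_internal_glucose_matches_reference(self):
        cs = fresh(80.0, 10.0)
        assert cs.model_glucose == pytest.approx(10.0, abs=1e-6)

    def test_weight_based_basal_prior(self):
        assert fresh(80.0).b_est == pytest.approx(0.02 * 80)

    def test_default_setpoint_is_band_midpoint(self):
        assert fresh().G_target == 7.0

    def test_rejects_absurd_reference(self):
        with pytest.raises(ValueError):
            C.initialize(80.0, 55.0)


class TestAssimilate:
    def test_zero_innovation_decays_flux_and_freezes_basal(self):
        cs = fresh(80.0, 7.0)
        cs.u_prev = cs.b_est  # model input = b_ref -> flat at its equilibrium
        cs.F_c = 0.8
        b0 = cs.b_est
        for _ in range(12):
            C.assimilate(cs, model_prediction_next(cs))
        assert abs(cs.F_c) < 0.8 * math.exp(-12 * 5 / 30.0) + 1e-9
        assert cs.b_est == pytest.approx(b0, abs=1e-9)

    def test_positive_innovation_raises_flux_and_basal(self):
        cs = fresh(80.0, 7.0)
        b = [cs.b_est]
        for _ in range(6):
            C.assimilate(cs, cs.model_glucose + 1.0 + 5.0)  # persistently high
            b.append(cs.b_est)
        assert cs.F_c > 0
        assert all(x < y for x, y in zip(b, b[1:]))

    def test_basal_estimate_clamped(self):
        cs = fresh(80.0, 7.0, K_b=10.0)
        for _ in range(10):
            C.assimilate(cs, 30.0)
        assert cs.b_est <= 50.0

    def test_non_finite_observation_rejected(self):
        cs = fresh()
        with pytest.raises(ValueError):
            C.assimilate(cs, float("nan"))


class TestPredict:
    def test_equilibrated_prediction_is_flat(self):
        cs = fresh(80.0, 7.0)
        traj = C.predict(cs, cs.b_est, 90.0)
        assert np.all(np.abs(traj - 7.0) < 0.05)

    def test_monotone_in_insulin(self):
        cs = fresh(80.0, 10.0)
        hi = C.predict(cs, 50.0, 90.0)
        lo = C.predict(cs, 0.0, 90.0)
        assert np.all(hi <= lo)
        assert np.all(np.diff(hi) <= 0)  # huge dose: falls until the 0 floor
        assert hi[3] < hi[0]

    def test_bad_horizon_rejected(self):
        with pytest.raises(ValueError):
            C.predict(fresh(), 1.0, 0.0)


class TestComputeInsulin:
    def test_saturates_at_cap_when_very_hyperglycemic(self):
        cs = fresh(80.0, 10.0)
        cs.b_est = 45.0
        cs.u_prev = 45.0
        for _ in range(4):
            C.assimilate(cs, 25.0)
        assert C.compute_insulin(cs) == 50.0

    def test_suspend_below_offset_from_target(self):
        """Insulin is zero at observed glucose below target - 1.2 mM."""
        cs = fresh(80.0, 10.0)
        cs.last_obs = 5.79
        assert C.compute_insulin(cs) == 0.0
        assert C.is_insulin_suspended(cs, 5.79)
        assert not C.is_insulin_suspended(cs, 5.81)

    def test_tracks_basal_estimate_at_setpoint(self):
        """At the setpoint with a converged basal estimate, u* stays near b_est."""
        cs = fresh(80.0, 7.0)
        cs.u_prev = cs.b_est
        u = C.compute_insulin(cs)
        assert u == pytest.approx(cs.b_est, abs=0.3)

    def test_grid_matches_fine_brute_force(self):
        """Coarse 0.05-U/h argmin equals a 10x-finer brute force within one step."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            cs = fresh(80.0, float(rng.uniform(5, 20)))
            cs.F_c = float(rng.normal(0, 0.5))
            cs.b_est = float(rng.uniform(0, 8))
            cs.u_prev = float(rng.uniform(0, 10))
            cs.last_obs = cs.model_glucose
            coarse = C.compute_insulin(cs)
            fine = C.compute_insulin(cs, grid_step=0.005)
            assert abs(coarse - fine) <= 0.05 + 1e-9


class TestComputeDextrose:
    def test_zero_when_forecast_safe(self):
        cs = fresh(80.0, 7.0)
        assert C.compute_dextrose(cs) == 0.0

    def test_cap_binds_on_deep_forecast(self):
        cs = fresh(80.0, 10.0)
        for _ in range(6):
            C.assimilate(cs, 2.0)
        assert C.compute_dextrose(cs) == 200.0

    def test_mutual_exclusion_in_cycle(self):
        cs = fresh(80.0, 10.0)
        _, cmd = C.control_cycle(cs, 0, 2.0)
        assert cmd.dextrose > 0 and cmd.insulin == 0.0


class TestCalibrationSchedule:
    def test_low_glucose_interval(self):
        assert C.schedule_calibration(fresh(), 3.0, 0.5) == 30.0

    def test_small_deviation_longest_interval(self):
        assert C.schedule_calibration(fresh(), 8.0, 0.0) == 360.0

    def test_linear_interpolation(self):
        # 11% deviation: 60 + 300 * (20 - 11) / 18 = 210 min
        assert C.schedule_calibration(fresh(), 8.0, 0.11) == pytest.approx(210.0)

    def test_large_deviation_shortest_interval(self):
        assert C.schedule_calibration(fresh(), 8.0, 0.5) == 60.0


class TestControlCycle:
    def test_off_grid_rejected(self):
        with pytest.raises(C.OffGridError):
            C.control_cycle(fresh(), 7, 8.0)

    def test_fallback_when_sensor_unavailable(self):
        cs = fresh(80.0, 9.0)
        _, cmd = C.control_cycle(cs, 0, None)
        assert cmd.basis == "reference-fallback"
        assert cs.mode == "reference-fallback"

    def test_command_invariants_under_random_observations(self):
        """Across random observation streams, no command breaches a safety rule."""
        rng = np.random.default_rng(3)
        cs = fresh(80.0, 10.0)
        g = 10.0
        for k in range(1000):
            g = float(np.clip(g + rng.normal(0, 0.4), 1.2, 30.0))
            reading = g if rng.random() > 0.1 else None
            _, cmd = C.control_cycle(cs, 5 * k, reading,
                                     reference=g if k % 12 == 0 else None)
            assert 0.0 <= cmd.insulin <= 50.0
            assert 0.0 <= cmd.dextrose <= 200.0
            assert cmd.insulin * cmd.dextrose == 0.0
            if reading is not None and reading < cs.G_target - 1.2:
                assert cmd.insulin == 0.0

    def test_dose_command_validation(self):
        with pytest.raises(ValueError):
            C.DoseCommand(t=0, insulin=51.0, dextrose=0.0, basis="sensor")
        with pytest.raises(ValueError):
            C.DoseCommand(t=0, insulin=1.0, dextrose=10.0, basis="sensor")


class TestClosedLoopOnPatient:
    def run_loop(self, p, cho, hours, cs=None):
        state = steady_state(p, p.basal_insulin, CHO=cho)
        cs = cs or C.initialize(p.weight, state.glucose(p))
        u = dex = 0.0
        trace = []
        for t in range(hours * 60):
            G = state.glucose(p)
            if t % 5 == 0:
                _, cmd = C.control_cycle(cs, t, G)
                u, dex = cmd.insulin, cmd.dextrose
            state = step(state, p, ExogenousInput(u, dex, cho), 1.0)
            trace.append(state.glucose(p))
        return np.array(trace), cs

    def test_deterministic_regulation_into_band(self):
        """A noise-free subject reaches 6.0-8.0 mM within 12 h and stays close."""
        p = replace(make_cohort(1, seed=11)[0],
                    resistance_profile=ConstantResistance(1.0))
        trace, _ = self.run_loop(p, cho=7.5, hours=24)
        in_band = np.flatnonzero((trace >= 6.0) & (trace <= 8.0))
        assert in_band.size and in_band[0] < 12 * 60
        after = trace[12 * 60:]
        assert np.all((after >= 5.5) & (after <= 8.5))

    def test_basal_estimate_recovers_true_requirement(self):
        """After 24 h of constant conditions, b_est lands within +/-20% of the
        closed-form steady insulin requirement, across 10 random subjects."""
        cohort = make_cohort(10, seed=5)
        for p0 in cohort:
            p = replace(p0, resistance_profile=ConstantResistance(1.0))
            b_true = basal_for_glucose(p, 7.0, CHO=7.5)
            _, cs = self.run_loop(p, cho=7.5, hours=24)
            assert abs(cs.b_est / b_true - 1.0) <= 0.20, p0.subject_id


class TestReplay:
    def test_replay_is_deterministic(self):
        import pandas as pd

        t = np.arange(0, 360, 5.0)
        frame = pd.DataFrame({
            "t_min": t,
            "sensor_mM": np.where(t >= 60, 9.0 - t / 200.0, np.nan),
            "reference_mM": np.where(t % 60 == 0, 9.5, np.nan),
        })
        a = C.replay(frame, weight=80.0)
        b = C.replay(frame, weight=80.0)
        assert a.equals(b)
        assert len(a) == len(t)
        assert set(a.loc[a.t_min < 60, "basis"]) == {"reference-fallback"}
        assert set(a.loc[a.t_min >= 60, "basis"]) == {"sensor"}
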