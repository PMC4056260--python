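"""Virtual-patient kinetics: structure, equilibria, integrator accuracy,
mass conservation and cohort generation."""

from dataclasses import replace

import numpy as np
import pytest

from iculoop.patient import (
    DEXTROSE_G_PER_ML,
    MMOL_PER_G,
    CohortConfig,
    ConstantResistance,
    ExogenousInput,
    NoEquilibriumError,
    PatientState,
    SinusoidResistance,
    basal_for_glucose,
    derivatives,
    make_cohort,
    nominal_params,
    steady_state,
    steady_state_glucose,
    step,
)
from iculoop.patient import _rhs


def euler_trajectory(state, params, inp, total_min, dt):
    """Independent fine-step forward-Euler integration of the same dynamics."""
    y = state.as_vector()
    args = (params, inp.insulin_rate * 1000 / 60,
            inp.dextrose_rate * DEXTROSE_G_PER_ML * MMOL_PER_G / 60,
            inp.enteral_CHO * MMOL_PER_G / 60)
    t = state.t
    n = int(round(total_min / dt))
    for _ in range(n):
        y = y + dt * _rhs(y, t, *args)
        t += dt
    return PatientState.from_vector(y, t)


class TestDerivatives:
    def test_structural_identity_at_rest(self, pop80):
        """With no insulin action and no inputs, dQ1 = -F01*w + EGP0*w."""
        s = PatientState(Q1=100.0, Q2=0.0, I=0.0, x1=0.0, x2=0.0, x3=0.0)
        d = derivatives(s, pop80, ExogenousInput())
        w = pop80.weight
        assert d.Q1 == pytest.approx(-pop80.F01 * w + pop80.EGP0 * w)
        assert d.Q2 == 0.0 and d.I == pytest.approx(0.0)

    def test_dextrose_unit_conversion(self, pop80):
        """200 mL/h of 20% dextrose is 40 g/h = 3.70 mmol/min appearance."""
        s = PatientState(Q1=100.0, Q2=0.0, I=0.0, x1=0.0, x2=0.0, x3=0.0)
        base = derivatives(s, pop80, ExogenousInput())
        fed = derivatives(s, pop80, ExogenousInput(dextrose_rate=200.0))
        assert fed.Q1 - base.Q1 == pytest.approx(200 * 0.2 * 5.551 / 60, abs=1e-12)
        assert fed.Q1 - base.Q1 == pytest.approx(3.70, abs=0.01)

    def test_enteral_cho_enters_gut_not_plasma(self, pop80):
        s = PatientState(Q1=100.0, Q2=0.0, I=0.0, x1=0.0, x2=0.0, x3=0.0, gut=0.0)
        d = derivatives(s, pop80, ExogenousInput(enteral_CHO=6.0))
        assert d.gut == pytest.approx(6.0 * MMOL_PER_G / 60)

    def test_degenerate_state_rejected(self, pop80):
        s = PatientState(Q1=float("nan"), Q2=0, I=0, x1=0, x2=0, x3=0)
        with pytest.raises(ValueError):
            derivatives(s, pop80, ExogenousInput())


class TestSteadyState:
    def test_derivatives_vanish_at_equilibrium(self, pop80):
        st = steady_state(pop80, insulin_rate=2.0, CHO=6.0)
        d = derivatives(st, pop80, ExogenousInput(insulin_rate=2.0, enteral_CHO=6.0))
        for name in ("Q1", "Q2", "I", "x1", "x2", "x3", "gut"):
            assert abs(getattr(d, name)) < 1e-9, name

    def test_no_equilibrium_without_insulin_action(self, pop80):
        p = replace(pop80, S_IT=0.0, S_ID=0.0, S_IE=0.0)
        with pytest.raises(NoEquilibriumError):
            steady_state_glucose(p, insulin_rate=5.0, CHO=10.0)

    def test_glucose_strictly_decreasing_in_insulin(self, pop80):
        us = np.linspace(1.0, 3.0, 9)
        gs = [steady_state_glucose(pop80, u, CHO=7.5) for u in us]
        assert all(a > b for a, b in zip(gs, gs[1:]))

    def test_basal_inversion_round_trips(self, pop80):
        u = basal_for_glucose(pop80, 7.0, CHO=7.5)
        assert steady_state_glucose(pop80, u, CHO=7.5) == pytest.approx(7.0, abs=1e-8)


class TestStep:
    def test_equilibrium_is_fixed_point(self, pop80):
        st = steady_state(pop80, 2.0, CHO=6.0)
        inp = ExogenousInput(insulin_rate=2.0, enteral_CHO=6.0)
        out = step(st, pop80, inp, dt=1.0)
        assert out.glucose(pop80) == pytest.approx(st.glucose(pop80), abs=1e-9)

    def test_invalid_dt_rejected(self, pop80):
        st = steady_state(pop80, 2.0, CHO=6.0)
        with pytest.raises(ValueError):
            step(st, pop80, ExogenousInput(), dt=0.0)

    def test_short_horizon_matches_fine_euler(self, pop80):
        """10 one-minute RK4 steps agree with dt=0.001 Euler within 1e-4 mM."""
        st = steady_state(pop80, 2.0, CHO=6.0)
        inp = ExogenousInput(insulin_rate=4.0, enteral_CHO=6.0)
        rk = st
        for _ in range(10):
            rk = step(rk, pop80, inp, dt=1.0)
        eu = euler_trajectory(st, pop80, inp, total_min=10.0, dt=0.001)
        assert rk.glucose(pop80) == pytest.approx(eu.glucose(pop80), abs=1e-4)

    def test_six_hour_run_matches_fine_euler(self, pop80):
        """RK4 at dt=1 min tracks dt=0.001 Euler within 0.01 mM over 6 h."""
        st = steady_state(pop80, 2.0, CHO=6.0)
        for inp in (ExogenousInput(insulin_rate=5.0, enteral_CHO=6.0),
                    ExogenousInput(insulin_rate=0.5, enteral_CHO=10.0)):
            rk = st
            for _ in range(180):
                rk = step(rk, pop80, inp, dt=1.0)
            eu = euler_trajectory(st, pop80, inp, total_min=180.0, dt=0.001)
            assert rk.glucose(pop80) == pytest.approx(eu.glucose(pop80), abs=0.01)

    def test_monotone_dose_response_in_simulation(self, pop80):
        """Mean simulated glucose is non-increasing in the constant insulin rate."""
        st = steady_state(pop80, 1.5, CHO=7.5)
        means = []
        for u in (0.0, 1.0, 2.0, 3.0, 5.0, 10.0):
            s = st
            tot = 0.0
            for _ in range(360):
                s = step(s, pop80, ExogenousInput(insulin_rate=u, enteral_CHO=7.5))
                tot += s.glucose(pop80)
            means.append(tot)
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_nonnegative_under_nonnegative_inputs(self, pop80):
        """Heavy insulin with no feeding drives glucose to 0 but never below."""
        s = steady_state(pop80, 2.0, CHO=6.0)
        for t in range(720):
            s = step(s, pop80, ExogenousInput(insulin_rate=50.0))
            assert min(s.Q1, s.Q2, s.I, s.x1, s.x2, s.x3, s.gut) >= 0.0

    def test_mass_conservation_without_sinks(self):
        """With uptake/production switched (almost) off, glucose mass tracks inputs."""
        p = nominal_params(80.0, F01=1e-12, EGP0=1e-12, S_IT=1e-15,
                           S_ID=1e-15, S_IE=1e-15)
        s = PatientState(Q1=100.0, Q2=20.0, I=0.0, x1=0, x2=0, x3=0, gut=5.0)
        inp = ExogenousInput(dextrose_rate=50.0, enteral_CHO=5.0)
        m0 = s.Q1 + s.Q2 + s.gut
        minutes = 720
        for _ in range(minutes):
            s = step(s, p, inp)
        influx = (50.0 * 0.2 + 5.0) * MMOL_PER_G / 60 * minutes
        m1 = s.Q1 + s.Q2 + s.gut
        assert m1 - m0 == pytest.approx(influx, rel=1e-3)


class TestCohort:
    def test_same_seed_identical(self):
        a = make_cohort(10, seed=7)
        b = make_cohort(10, seed=7)
        for pa, pb in zip(a, b):
            assert replace(pa, resistance_profile=None) == \
                replace(pb, resistance_profile=None)
            assert pa.resistance_profile == pb.resistance_profile

    def test_diabetes_fraction(self):
        cohort = make_cohort(1000, seed=1)
        frac = np.mean([p.diabetes for p in cohort])
        assert abs(frac - 0.46) < 0.05

    def test_invariants_hold(self, small_cohort):
        for p in small_cohort:
            assert 40 <= p.weight <= 200
            assert p.V_G > 0 and p.k_e > 0 and p.k12 > 0
            assert p.S_IT > 0 and p.S_ID > 0 and p.S_IE > 0
            prof = p.resistance_profile
            assert isinstance(prof, SinusoidResistance)
            vals = [prof(t) for t in np.linspace(0, 2880, 97)]
            assert 0.2 <= min(vals) and max(vals) <= 3.0

    def test_baseline_anchoring(self, small_cohort):
        """Each subject's sampled basal rate really holds the sampled entry glucose."""
        cfg = CohortConfig()
        for p in small_cohort:
            g = steady_state_glucose(p, p.basal_insulin, CHO=cfg.cho_ref)
            assert g == pytest.approx(p.baseline_glucose, abs=1e-5)
            assert 8.0 <= g <= 14.0

    def test_entry_glucose_hyperglycemic(self, small_cohort):
        gs = [p.baseline_glucose for p in small_cohort]
        assert 9.0 <= float(np.median(gs)) <= 12.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            make_cohort(5, 0, CohortConfig(diabetes_p=1.5))
        with pytest.raises(ValueError):
            make_cohort(0, 0)
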