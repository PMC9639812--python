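"""Forward-model unit and property tests: killing, growth, secretion, CM."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from odelay import (
    DEFAULT_GROWTH,
    HICA,
    MVA_2K3,
    Condition,
    GrowthParams,
    ToxinResponse,
)
from odelay.popdyn import (
    cm_condition,
    combined_dose,
    default_secretion,
    kill_fraction,
    secrete_toxin,
    simulate_culture,
    tau_forward,
)

LN2 = math.log(2.0)


class TestKillFraction:
    def test_no_toxin_no_kill(self):
        assert kill_fraction(0.0, HICA, Condition()) == 0.0

    def test_critical_concentration_kills_everything(self):
        # growth fully suppressed at the critical dose (30 mM for HICA)
        assert kill_fraction(30.0, HICA, Condition()) == 1.0
        assert kill_fraction(25.0, MVA_2K3, Condition()) == 1.0

    def test_glucose_fully_protects(self):
        assert kill_fraction(40.0, HICA, Condition(glucose_present=True)) == 0.0

    def test_adaptation_fully_protects(self):
        assert kill_fraction(40.0, HICA, Condition(adapted=True)) == 0.0

    def test_subcritical_hill_value(self):
        c = 20.0  # at the half-effect concentration the Hill term is 1/2
        assert kill_fraction(c, HICA, Condition()) == pytest.approx(HICA.d_max / 2)

    def test_cm_background_applies_potency_multiplier(self):
        cond = Condition(cm_background=True)
        assert kill_fraction(0.05, HICA, cond) == kill_fraction(50.0, HICA, Condition())

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            kill_fraction(-1.0, HICA, Condition())

    @given(st.floats(0.0, 60.0), st.floats(0.0, 60.0))
    def test_monotone_in_dose(self, c1, c2):
        lo, hi = sorted((c1, c2))
        assert kill_fraction(lo, HICA) <= kill_fraction(hi, HICA)


class TestCombinedDose:
    def test_single_dose_identity(self):
        assert combined_dose([(12.0, HICA)]) == pytest.approx(12.0)

    def test_mixture_adds_on_normalised_scale(self):
        # half of each critical concentration adds to one full critical dose
        c = combined_dose([(15.0, HICA), (12.5, MVA_2K3)])
        assert kill_fraction(c, HICA) == 1.0


class TestSimulateCulture:
    def test_od_is_living_plus_dead_and_dead_constant(self):
        traj = simulate_culture(DEFAULT_GROWTH, 0.4, horizon=30.0)
        np.testing.assert_allclose(traj.od, traj.living + traj.dead, rtol=0, atol=0)
        assert np.all(traj.dead == traj.dead[0])
        assert traj.dead[0] == pytest.approx(DEFAULT_GROWTH.a0 * 0.4)

    def test_pure_exponential_limit(self):
        # d=0, K huge: OD(t) = a0 e^{rt} within 1e-9 relative
        p = GrowthParams(r=LN2 / 10, lag=0.0, K=1e9, a0=0.005)
        traj = simulate_culture(p, 0.0, horizon=3.0 / p.r, step=0.5)
        expected = p.a0 * np.exp(p.r * traj.t)
        np.testing.assert_allclose(traj.od, expected, rtol=1e-6)

    def test_total_kill_is_flat_at_a0(self):
        traj = simulate_culture(DEFAULT_GROWTH, 1.0, horizon=50.0)
        np.testing.assert_allclose(traj.od, DEFAULT_GROWTH.a0, rtol=0, atol=0)

    def test_doubling_time_with_two_thirds_killed(self):
        # first OD crossing of 2*a0 at tau = ln((2-d)/(1-d))/r = 20 h
        p = GrowthParams(r=LN2 / 10, lag=0.0, K=1e9, a0=0.005)
        traj = simulate_culture(p, 2.0 / 3.0, horizon=30.0, step=0.001)
        i = int(np.argmax(traj.od >= 2 * p.a0))
        assert traj.t[i] == pytest.approx(20.0, abs=0.002)

    def test_kill_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_culture(DEFAULT_GROWTH, 1.2, horizon=10.0)

    def test_lag_delays_growth(self):
        p = DEFAULT_GROWTH.replace(lag=5.0)
        traj = simulate_culture(p, 0.0, horizon=10.0)
        flat = traj.t <= 5.0
        np.testing.assert_allclose(traj.od[flat], p.a0)
        assert traj.od[-1] > p.a0


class TestTauForward:
    def test_doubling_time_of_pure_exponential(self):
        p = GrowthParams(r=LN2 / 10, K=1e9, a0=0.005)
        assert tau_forward(p, 0.0) == pytest.approx(10.0, abs=1e-6)

    def test_two_thirds_killed_doubles_at_twenty_hours(self):
        p = GrowthParams(r=LN2 / 10, K=1e9, a0=0.005)
        assert tau_forward(p, 2.0 / 3.0) == pytest.approx(20.0, abs=1e-5)

    def test_total_kill_is_censored(self):
        assert math.isinf(tau_forward(DEFAULT_GROWTH, 1.0))

    def test_censored_when_cap_below_double(self):
        p = GrowthParams(r=0.1, K=0.009, a0=0.005)
        assert math.isinf(tau_forward(p, 0.0))

    def test_lag_shifts_tau_additively(self):
        base = tau_forward(DEFAULT_GROWTH, 0.3)
        lagged = tau_forward(DEFAULT_GROWTH.replace(lag=4.0), 0.3)
        assert lagged == pytest.approx(base + 4.0)

    def test_matches_simulation_root_finding(self):
        # closed form vs brute-force scan of the simulated trajectory
        rng = np.random.default_rng(42)
        for _ in range(100):
            p = GrowthParams(
                r=rng.uniform(0.03, 0.15),
                lag=rng.uniform(0.0, 5.0),
                K=1.0,
                a0=rng.uniform(0.002, 0.02),
            )
            d = rng.uniform(0.0, 0.9)
            tau = tau_forward(p, d)
            traj = simulate_culture(p, d, horizon=tau + 2.0, step=0.0005)
            i = int(np.argmax(traj.od >= 2 * p.a0))
            assert traj.t[i] == pytest.approx(tau, abs=1e-3)

    def test_monotone_in_kill_fraction_and_rate(self):
        for r in np.arange(0.03, 0.16, 0.03):
            p = GrowthParams(r=float(r), K=1.0, a0=0.005)
            taus = [tau_forward(p, d) for d in np.arange(0.0, 0.95, 0.1)]
            assert all(t2 > t1 for t1, t2 in zip(taus, taus[1:]))
        for d in np.arange(0.0, 0.95, 0.1):
            taus = [
                tau_forward(GrowthParams(r=float(r), K=1.0, a0=0.005), float(d))
                for r in np.arange(0.03, 0.16, 0.03)
            ]
            assert all(t2 < t1 for t1, t2 in zip(taus, taus[1:]))


class TestSecretion:
    def test_zero_before_induction(self, growth, secretion):
        assert secrete_toxin(growth, secretion, 0.0) == 0.0
        assert secrete_toxin(growth, secretion, secretion.t_ind) == 0.0

    def test_reported_fold_change_bounds(self, growth, secretion):
        c10 = secrete_toxin(growth, secretion, 10.0)
        c20 = secrete_toxin(growth, secretion, 20.0)
        c30 = secrete_toxin(growth, secretion, 30.0)
        assert c20 / c10 > 5.0
        assert c30 / c20 > 3.0

    def test_closed_form_matches_quadrature(self, growth, secretion):
        for t_inc in (10.0, 20.0, 30.0):
            numeric, _ = quad(
                lambda u: secretion.k * (growth.a0 * math.exp(growth.r * u)) ** 2,
                secretion.t_ind,
                t_inc,
            )
            assert secrete_toxin(growth, secretion, t_inc) == pytest.approx(
                numeric, rel=1e-9
            )

    def test_strictly_increasing_past_induction(self, growth, secretion):
        vals = [secrete_toxin(growth, secretion, t) for t in np.arange(3.0, 40.0, 2.0)]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestCMCondition:
    def test_zero_signal_zero_dose(self, growth, secretion):
        assert cm_condition(0.0, secretion, HICA, growth).effective_dose == 0.0

    def test_thirty_hour_cm_kills_two_thirds(self, growth, secretion):
        signal = secrete_toxin(growth, secretion, 30.0)
        cond = cm_condition(signal, secretion, HICA, growth)
        d = kill_fraction(cond.effective_dose, HICA, cond)
        assert d == pytest.approx(2.0 / 3.0, abs=1e-9)
        # downstream: survivors double the OD after ~20 h
        assert tau_forward(growth, d) == pytest.approx(20.0, abs=0.2)

    def test_short_incubation_below_killing_range(self, growth, secretion):
        signal = secrete_toxin(growth, secretion, 10.0)
        cond = cm_condition(signal, secretion, HICA, growth)
        d = kill_fraction(cond.effective_dose, HICA, cond)
        assert tau_forward(growth, d) < tau_forward(growth, 0.0) + 0.5

    def test_dose_monotone_in_signal(self, growth, secretion):
        doses = [
            cm_condition(s, secretion, HICA, growth).effective_dose
            for s in np.linspace(0.0, 80.0, 30)
        ]
        assert all(b >= a for a, b in zip(doses, doses[1:]))

    def test_threshold_separates_delay_induction(self, growth, secretion):
        # delay-inducing kill (>0.45 or so) iff the signal exceeds E_thresh
        for t_inc in (5.0, 10.0, 15.0):
            s = secrete_toxin(growth, secretion, t_inc)
            assert s < secretion.E_thresh
            cond = cm_condition(s, secretion, HICA, growth)
            assert kill_fraction(cond.effective_dose, HICA, cond) < 0.01
        for t_inc in (20.0, 25.0, 30.0):
            s = secrete_toxin(growth, secretion, t_inc)
            assert s > secretion.E_thresh
            cond = cm_condition(s, secretion, HICA, growth)
            assert kill_fraction(cond.effective_dose, HICA, cond) > 0.5


class TestParameterValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(r=-0.1),
            dict(r=0.07, lag=-1.0),
            dict(r=0.07, a0=0.0),
            dict(r=0.07, a0=2.0, K=1.0),
        ],
    )
    def test_growth_params_invariants(self, kwargs):
        with pytest.raises(ValueError):
            GrowthParams(**kwargs)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(c_crit=30.0, h=35.0),
            dict(c_crit=30.0, h=20.0, n=0.5),
            dict(c_crit=30.0, h=20.0, d_max=1.0),
            dict(c_crit=30.0, h=20.0, s=0.5),
        ],
    )
    def test_toxin_response_invariants(self, kwargs):
        with pytest.raises(ValueError):
            ToxinResponse(**kwargs)
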