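"""Two-label competition: closed-form steady state vs simulation, fractions."""

import math

import numpy as np
import pytest

from odelay import DEFAULT_GROWTH, GrowthParams
from odelay.competition import (
    CompetitionModel,
    Competitor,
    compare_prediction,
    fraction_timecourse,
    predict_steady_state,
)
from odelay.containers import FlowSample
from odelay.params import CultureState
from odelay.synth import generate_flow_counts

LN2 = math.log(2.0)


class TestPredictSteadyState:
    def test_identical_adapted_populations_split_fifty_fifty(self):
        adapted = Competitor(DEFAULT_GROWTH, 0.0, "A")
        pred = predict_steady_state(adapted, Competitor(DEFAULT_GROWTH, 0.0, "B"))
        assert pred.f_inf == 0.5
        assert np.allclose(pred.f_t, 0.5, atol=1e-12)

    def test_two_thirds_kill_gives_three_quarters(self):
        a = Competitor(DEFAULT_GROWTH, 0.0, "A")
        b = Competitor(DEFAULT_GROWTH, 2.0 / 3.0, "B")
        pred = predict_steady_state(a, b)
        assert pred.f_inf == pytest.approx(0.75, abs=1e-12)
        # closed form must match the simulated long-time fraction
        assert pred.f_t[-1] == pytest.approx(0.75, abs=1e-4)

    def test_one_sided_inoculum(self):
        a = Competitor(DEFAULT_GROWTH, 0.0, "A")
        b = Competitor(DEFAULT_GROWTH, 0.0, "B")
        assert predict_steady_state(a, b, (1.0, 0.0)).f_inf == 1.0

    def test_swap_symmetry(self):
        a = Competitor(DEFAULT_GROWTH, 0.1, "A")
        b = Competitor(DEFAULT_GROWTH, 0.6, "B")
        f_ab = predict_steady_state(a, b, (2.0, 1.0)).f_inf
        f_ba = predict_steady_state(b, a, (1.0, 2.0)).f_inf
        assert f_ab == pytest.approx(1.0 - f_ba, abs=1e-12)

    def test_closed_form_matches_simulation_on_random_grid(self):
        # the closed form discounts lags by e^{-r lag}, exact in the
        # pre-saturation regime (inoculum << K), hence the small a0 draws
        rng = np.random.default_rng(7)
        for _ in range(10):
            r = rng.uniform(0.04, 0.12)
            p = GrowthParams(r=r, K=1.0, a0=rng.uniform(1e-4, 5e-4))
            a = Competitor(p.replace(lag=rng.uniform(0, 3)), rng.uniform(0, 0.8), "A")
            b = Competitor(p.replace(lag=rng.uniform(0, 3)), rng.uniform(0, 0.8), "B")
            pred = predict_steady_state(a, b, horizon=250.0)
            assert pred.f_t[-1] == pytest.approx(pred.f_inf, abs=1e-4)

    def test_lag_discounts_inoculum_weight(self):
        a = Competitor(DEFAULT_GROWTH.replace(lag=10.0), 0.0, "A")
        b = Competitor(DEFAULT_GROWTH, 0.0, "B")
        expected = math.exp(-DEFAULT_GROWTH.r * 10.0)
        pred = predict_steady_state(a, b)
        assert pred.f_inf == pytest.approx(expected / (1 + expected), abs=1e-9)

    def test_unequal_rates_flagged_degenerate(self):
        a = Competitor(DEFAULT_GROWTH, 0.0, "A")
        b = Competitor(DEFAULT_GROWTH.replace(r=0.09), 0.0, "B")
        pred = predict_steady_state(a, b)
        assert pred.degenerate
        assert pred.f_inf == 0.0  # the faster grower takes over

    def test_fractions_sum_to_one(self):
        a = Competitor(DEFAULT_GROWTH, 0.2, "A")
        b = Competitor(DEFAULT_GROWTH, 0.5, "B")
        pred_a = predict_steady_state(a, b)
        pred_b = predict_steady_state(b, a)
        np.testing.assert_allclose(pred_a.f_t + pred_b.f_t, 1.0, atol=1e-12)


class TestFractionTimecourse:
    def test_even_counts_give_half(self):
        s = FlowSample("t0", 0.0, {"green_live": 250_000, "red_live": 250_000})
        df = fraction_timecourse([s], "green")
        assert df["fraction"].iloc[0] == 0.5
        assert df["se"].iloc[0] == pytest.approx(math.sqrt(0.25 / 500_000))

    def test_absent_label_fraction_zero(self):
        s = FlowSample("t0", 0.0, {"green_live": 0, "red_live": 1000})
        assert fraction_timecourse([s], "green")["fraction"].iloc[0] == 0.0

    def test_dead_gates_excluded_by_default(self):
        s = FlowSample(
            "t0", 0.0,
            {"green_live": 100, "red_live": 100, "green_dead": 800},
        )
        df = fraction_timecourse([s], "green")
        assert df["fraction"].iloc[0] == 0.5
        df_all = fraction_timecourse([s], "green", include_dead=True)
        assert df_all["fraction"].iloc[0] == 0.9

    def test_samples_sorted_by_time(self):
        s1 = FlowSample("b", 12.0, {"green_live": 300, "red_live": 100})
        s0 = FlowSample("a", 0.0, {"green_live": 200, "red_live": 200})
        df = fraction_timecourse([s1, s0], "green")
        assert list(df["t"]) == [0.0, 12.0]

    def test_adapted_fraction_rises_to_steady_state(self):
        # adapted cells overtake unadapted ones killed at 2/3, then plateau
        a = Competitor(DEFAULT_GROWTH, 0.0, "green")
        b = Competitor(DEFAULT_GROWTH, 2.0 / 3.0, "red")
        pred = predict_steady_state(a, b, horizon=48.0)
        idx = [int(np.argmin(np.abs(pred.t - h))) for h in (0, 6, 12, 24, 48)]
        fr = pred.f_t[idx]
        assert all(b2 >= b1 - 1e-12 for b1, b2 in zip(fr, fr[1:]))
        assert fr[0] == pytest.approx(1.0 / (1.0 + 1.0 / 3.0), abs=1e-9)


class TestComparePrediction:
    def _samples_from(self, pred, seed=0, times=(0, 12, 24, 36, 48)):
        rng = np.random.default_rng(seed)
        samples = []
        for i, h in enumerate(times):
            j = int(np.argmin(np.abs(pred.t - h)))
            states = {
                "green": CultureState(float(pred.trajectory_a[j]), 0.0, float(h)),
                "red": CultureState(float(pred.trajectory_b[j]), 0.0, float(h)),
            }
            samples.append(
                generate_flow_counts(states, 500_000, count_dead=False, seed=rng,
                                     sample_id=f"s{i}")
            )
        return samples

    def test_self_consistency_at_generator_truth(self):
        a = Competitor(DEFAULT_GROWTH, 0.0, "green")
        b = Competitor(DEFAULT_GROWTH, 2.0 / 3.0, "red")
        pred = predict_steady_state(a, b, horizon=48.0)
        obs = fraction_timecourse(self._samples_from(pred), "green")
        rep = compare_prediction(pred, obs)
        assert rep.agree
        assert rep.max_abs_deviation < 0.01

    def test_wrong_prediction_flagged(self):
        a = Competitor(DEFAULT_GROWTH, 0.0, "green")
        b = Competitor(DEFAULT_GROWTH, 2.0 / 3.0, "red")
        pred = predict_steady_state(a, b, horizon=48.0)
        obs = fraction_timecourse(self._samples_from(pred), "green")
        obs["fraction"] = 0.5  # flat observation cannot match the rise to 0.75
        rep = compare_prediction(pred, obs)
        assert not rep.agree
        assert rep.max_abs_deviation > 0.2

    def test_single_shared_timepoint(self):
        a = Competitor(DEFAULT_GROWTH, 0.0, "green")
        b = Competitor(DEFAULT_GROWTH, 0.0, "red")
        pred = predict_steady_state(a, b, horizon=10.0)
        obs = fraction_timecourse(
            [FlowSample("one", 5.0, {"green_live": 251_000, "red_live": 249_000})],
            "green",
        )
        rep = compare_prediction(pred, obs)
        assert rep.n_points == 1


class TestCompetitionModel:
    def test_model_fit_summary(self):
        a = Competitor(DEFAULT_GROWTH, 0.0, "green")
        b = Competitor(DEFAULT_GROWTH, 2.0 / 3.0, "red")
        res = CompetitionModel(a, b, horizon=48.0).fit()
        assert res.f_inf == pytest.approx(0.75, abs=1e-9)
        assert "f_inf" in res.summary()
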