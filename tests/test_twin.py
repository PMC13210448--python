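"""Digital-twin dynamics, calibration and goodness of fit."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aquatwin import twin


def null_params(**kw) -> twin.TwinParameters:
    base = dict(
        kLa=0.0, kLa_ambient=0.0, DOsat=8.0, Rresp=0.0,
        nit_mode="constant", Rnit=0.0, gamma_O2=1.0,
        feed_rate=0.0, feed_background=0.0,
        dil_mode="constant", Rdil=0.0, dt=1.0 / 12.0,
    )
    base.update(kw)
    return twin.TwinParameters(**base)


class TestStep:
    def test_null_dynamics_leave_state_unchanged(self):
        s = twin.TwinState(6.0, 0.2)
        out = twin.step(s, null_params(), 1, 1)
        assert out.DO == 6.0 and out.NH3 == 0.2

    def test_saturated_do_is_equilibrium(self):
        p = null_params(kLa=0.6)
        out = twin.step(twin.TwinState(8.0, 0.0), p, 1, 0)
        assert out.DO == pytest.approx(8.0)

    def test_do_euler_update_hand_value(self):
        # DO = 6 + (1/12) * (0.6*(8-6) - 0.1 - 0.05) = 6.0875
        p = null_params(kLa=0.6, Rresp=0.1, Rnit=0.05)
        out = twin.step(twin.TwinState(6.0, 0.2), p, 1, 0)
        assert out.DO == pytest.approx(6.0875, abs=1e-12)

    def test_nh3_euler_update_hand_value(self):
        # NH3 = 0.2 + (1/12) * (0.12 - 0.05 - 0.01) = 0.205
        p = null_params(Rnit=0.05, Rdil=0.01, feed_rate=0.12)
        out = twin.step(twin.TwinState(6.0, 0.2), p, 1, 1)
        assert out.NH3 == pytest.approx(0.205, abs=1e-12)

    def test_undershoot_clamped_at_zero(self):
        p = null_params(Rresp=100.0)
        out = twin.step(twin.TwinState(0.5, 0.0), p, 0, 0)
        assert out.DO == 0.0

    def test_non_finite_state_raises(self):
        with pytest.raises(twin.NumericError):
            twin.step(twin.TwinState(float("nan"), 0.1), null_params(), 0, 0)


class TestSimulate:
    def test_single_step_equals_step(self):
        p = null_params(kLa=0.6, Rresp=0.1)
        s0 = twin.TwinState(6.0, 0.2)
        traj = twin.simulate(s0, p, [(1, 0)], 1)
        direct = twin.step(s0, p, 1, 0)
        assert len(traj) == 2
        assert traj[1].DO == direct.DO and traj[1].NH3 == direct.NH3

    def test_null_dynamics_constant_trajectory(self):
        traj = twin.simulate(twin.TwinState(5.0, 0.3), null_params(),
                             [(1, 1)] * 10, 10)
        assert all(s.DO == 5.0 and s.NH3 == 0.3 for s in traj)

    def test_matches_closed_form_linear_recurrence(self):
        # sinks off, aeration on: DO_n = DOsat - (DOsat - DO_0)(1 - dt*kLa)^n
        p = null_params(kLa=0.6)
        traj = twin.simulate(twin.TwinState(4.0, 0.0), p, [(1, 0)] * 50, 50)
        n = np.arange(51)
        closed = 8.0 - (8.0 - 4.0) * (1 - p.dt * 0.6) ** n
        sim = np.array([s.DO for s in traj])
        assert np.allclose(sim, closed, rtol=0, atol=1e-12)
        assert np.all(np.diff(sim) > 0)  # monotone approach

    def test_nonpositive_steps_rejected(self):
        with pytest.raises(ValueError):
            twin.simulate(twin.TwinState(6, 0.2), null_params(), [], 0)

    @settings(max_examples=30, deadline=None)
    @given(
        st.floats(min_value=0.01, max_value=2.0),
        st.floats(min_value=0.01, max_value=5.0),
    )
    def test_never_overshoots_saturation_from_below(self, kla, do0):
        # stability guard: dt*kLa < 1 keeps the update below DOsat
        p = null_params(kLa=kla)  # dt = 1/12 so dt*kLa <= 1/6
        traj = twin.simulate(twin.TwinState(do0, 0.0), p, [(1, 0)] * 30, 30)
        assert all(s.DO <= 8.0 + 1e-12 for s in traj)


class TestGoodnessOfFit:
    def test_perfect_fit(self):
        assert twin.goodness_of_fit([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_mean_predictor_scores_zero(self):
        obs = [1.0, 2.0, 3.0]
        assert twin.goodness_of_fit([2.0, 2.0, 2.0], obs) == pytest.approx(0.0)

    def test_hand_value(self):
        assert twin.goodness_of_fit([1, 2, 4], [1, 2, 3]) == pytest.approx(0.5)

    def test_constant_observed_rejected(self):
        with pytest.raises(ValueError):
            twin.goodness_of_fit([1, 2, 3], [2, 2, 2])


def _simulated_frame(params, n=864, do0=6.0, nh30=0.15, seed=None, sd=0.0):
    """5-min observed frame generated by the twin itself."""
    steps = np.arange(n)
    aer = (steps % 12 < 4).astype(float)
    feed = (steps % 96 < 6).astype(float)
    do, nh3 = twin.simulate_arrays(do0, nh30, params, aer, feed)
    if sd > 0:
        rng = np.random.default_rng(seed)
        do = do + rng.normal(0, sd, n + 1)
        nh3 = nh3 + rng.normal(0, sd, n + 1)
    idx = pd.date_range("2026-01-01", periods=n + 1, freq="5min", tz="UTC")
    frame = pd.DataFrame({"DO": do, "NH3": nh3}, index=idx)
    trace = np.stack([np.append(aer, 0), np.append(feed, 0)], axis=1)
    return frame, trace


TRUTH = twin.TwinParameters(
    kLa=0.9, kLa_ambient=0.03, DOsat=7.8, Rresp=0.22, k_nit=0.06,
    feed_rate=0.25, feed_background=0.004, k_dil=0.03, dt=1.0 / 12.0,
)


class TestCalibrate:
    def test_noiseless_self_consistency_recovery(self):
        frame, trace = _simulated_frame(TRUTH)
        base = replace(TRUTH, kLa=0.4, Rresp=0.10, k_nit=0.02)
        res = twin.calibrate(frame, trace, ["kLa", "Rresp", "k_nit"], base=base)
        assert res.success and res.identifiable
        for name in ("kLa", "Rresp", "k_nit"):
            rel = abs(getattr(res.params, name) - getattr(TRUTH, name))
            rel /= getattr(TRUTH, name)
            assert rel < 1e-3

    def test_constant_equilibrium_flags_non_identifiability(self):
        # kLa and Rresp only enter through kLa*(DOsat-DO)-Rresp; a constant
        # trace cannot separate them
        idx = pd.date_range("2026-01-01", periods=100, freq="5min", tz="UTC")
        frame = pd.DataFrame({"DO": np.full(100, 6.0), "NH3": np.full(100, 0.2)},
                             index=idx)
        trace = np.stack([np.ones(100), np.zeros(100)], axis=1)
        res = twin.calibrate(frame, trace, ["kLa", "Rresp"], base=TRUTH)
        assert not res.identifiable

    def test_short_window_rejected(self):
        frame, trace = _simulated_frame(TRUTH, n=10)
        with pytest.raises(twin.InsufficientDataError):
            twin.calibrate(frame, trace, ["kLa"], base=TRUTH)

    def test_bounds_respected(self):
        frame, trace = _simulated_frame(TRUTH)
        res = twin.calibrate(frame, trace, ["kLa"], bounds={"kLa": (0.0, 0.5)},
                             base=replace(TRUTH, kLa=0.3))
        assert res.params.kLa <= 0.5 + 1e-12

    def test_residual_report_written(self, tmp_path):
        frame, trace = _simulated_frame(TRUTH)
        res = twin.calibrate(frame, trace, ["kLa"], base=replace(TRUTH, kLa=0.5))
        out = tmp_path / "residuals.csv"
        res.residual_report(out)
        assert len(pd.read_csv(out)) == len(frame) - 1


class TestDoSaturation:
    def test_monotone_decreasing_in_temperature(self):
        temps = np.linspace(0, 40, 50)
        sat = twin.do_saturation(temps)
        assert np.all(np.diff(sat) < 0)
        assert 8.5 < twin.do_saturation(20.0) < 9.5  # ~9.1 mg/L at 20 C

    def test_parameter_roundtrip_yaml(self, tmp_path):
        path = tmp_path / "params.yaml"
        TRUTH.to_yaml(path)
        back = twin.TwinParameters.from_yaml(path)
        assert back == TRUTH
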