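"""Pursuit-model simulations: fixed points, closed-form transfer-function
equivalence, predictive filtering, reductions between model families, and
the polar model against a brute-force integrator."""

import numpy as np
import pytest

from pursuitkit.models import (
    PursuitParams,
    AVG_FIT_PARAMS,
    closed_form_frequency_response,
    fast_simulate_predictive,
    filter_predictive_acceleration,
    periodic_lowpass,
    predictive_drive,
    simulate_image_velocity_model,
    simulate_polar_model,
    simulate_predictive_model,
)
from pursuitkit.trajectories import SumOfSinesTrajectory, TargetTrajectory

T = 4.5


class _ConstVel(TargetTrajectory):
    """Constant-velocity pseudo-target (period only nominal)."""

    kind = "test"

    def __init__(self, vx, vy, period=T):
        self.vx, self.vy = vx, vy
        self.period = period

    def position(self, t):
        t = np.asarray(t, dtype=float)
        return np.stack([self.vx * t, self.vy * t], axis=-1)

    def velocity(self, t):
        t = np.asarray(t, dtype=float)
        return np.broadcast_to([self.vx, self.vy], t.shape + (2,)).copy()

    def acceleration(self, t):
        t = np.asarray(t, dtype=float)
        return np.zeros(t.shape + (2,))


def _gain_phase_at(trace, traj, harmonic, axis, t0=T, t1=2 * T):
    sel = (trace.t >= t0) & (trace.t < t1)
    e = np.fft.rfft(trace.v[sel, axis])
    g = np.fft.rfft(traj.velocity(trace.t[sel])[:, axis])
    H = e[harmonic] / g[harmonic]
    return abs(H), np.degrees(np.angle(H))


class TestImageVelocityModel:
    def test_constant_velocity_fixed_point(self):
        p = PursuitParams(a=6.0, g_x=0.8, g_y=0.8, tau_t=0.03, tau_e=0.10)
        tr = simulate_image_velocity_model(p, _ConstVel(12.0, -5.0), t_end=3.0)
        # steady state reached well after 10/a seconds
        assert np.allclose(tr.v[-1], [0.8 * 12.0, 0.8 * -5.0], rtol=1e-5)

    def test_first_order_step_response(self):
        a = 5.0
        p = PursuitParams(a=a, g_x=1.0, g_y=1.0, tau_t=0.0, tau_e=0.0)
        tr = simulate_image_velocity_model(p, _ConstVel(10.0, 0.0), t_end=1.0, rate=1000.0)
        i = int(round(1000 / a))  # t = 1/a
        assert tr.v[i, 0] == pytest.approx((1 - np.exp(-1)) * 10.0, rel=1e-3)

    def test_matches_closed_form_at_0p67hz(self):
        # single-axis sinusoid at the 3rd harmonic of the 4.5 s period
        from pursuitkit.trajectories import AxisSines, SumOfSinesSpec

        spec = SumOfSinesSpec(
            T, AxisSines(0, 0, 3, 5.0, 0.4), AxisSines(0, 0, 2, 0, 0)
        )
        traj = SumOfSinesTrajectory(spec)
        p = PursuitParams(a=6.2, g_x=0.73, g_y=0.73, tau_t=0.02, tau_e=0.12)
        tr = simulate_image_velocity_model(p, traj, t_end=2 * T)
        gain, phase = _gain_phase_at(tr, traj, 3, 0)
        H = closed_form_frequency_response(p, "eq1", 2 * np.pi * 3 / T)
        assert gain == pytest.approx(abs(H), rel=0.01)
        assert phase == pytest.approx(np.degrees(np.angle(H)), abs=1.0)


class TestPredictiveFilter:
    def test_dc_gain_unity(self):
        out = periodic_lowpass(np.full(256, 7.3), T, b=3.0)
        assert np.allclose(out, 7.3)

    def test_sinusoid_closed_form(self):
        b = 3.47
        k = 2
        w = 2 * np.pi * k / T
        t = np.linspace(0, T, 1024, endpoint=False)
        out = periodic_lowpass(np.sin(w * t), T, b)
        amp = np.abs(np.fft.rfft(out))[k] * 2 / 1024
        assert amp == pytest.approx(b / np.hypot(b, w), rel=1e-9)
        ph = np.angle(np.fft.rfft(out)[k]) - np.angle(np.fft.rfft(np.sin(w * t))[k])
        assert ph == pytest.approx(-np.arctan(w / b), abs=1e-9)

    def test_large_b_identity_limit(self, paths):
        # path 4 keeps its speed well above the floor, so the channel's
        # spectral content sits far below the b = 1000 1/s corner
        traj = SumOfSinesTrajectory(paths[4])
        ahat = filter_predictive_acceleration(traj, b=1000.0, channel="tangential")
        t = np.linspace(0, T, 257, endpoint=False)
        from pursuitkit.trajectories import tangential_normal_acceleration

        dec = tangential_normal_acceleration(
            traj.velocity(t), traj.acceleration(t)
        )
        ref = dec.tangential[:, None] * dec.t_hat
        err = np.max(np.abs(ahat(t) - ref)) / np.max(np.abs(ref))
        assert err < 0.01

    def test_invalid_inputs_rejected(self, ss_traj):
        with pytest.raises(ValueError):
            filter_predictive_acceleration(ss_traj, b=-1.0, channel="tangential")
        with pytest.raises(ValueError):
            filter_predictive_acceleration(ss_traj, b=3.0, channel="radial")


class TestPredictiveModel:
    def test_reduces_to_image_velocity_without_prediction(self, ss_traj):
        p4 = PursuitParams(a=7.0, g_x=0.6, g_y=0.5, c1=0.0, c2=0.0, tau=0.08)
        p1 = p4.replace(tau_t=0.08, tau_e=0.08)
        t4 = simulate_predictive_model(p4, ss_traj, t_end=3.0)
        t1 = simulate_image_velocity_model(p1, ss_traj, t_end=3.0)
        scale = np.max(np.abs(t1.v))
        assert np.max(np.abs(t4.v - t1.v)) / scale <= 1e-9

    def test_matches_closed_form_with_scalar_c(self, ss_traj):
        p = AVG_FIT_PARAMS.replace(c1=0.29, c2=0.29)
        tr = simulate_predictive_model(p, ss_traj, t_end=2 * T)
        for axis, k in ((0, 1), (0, 3), (1, 1), (1, 2)):
            gain, phase = _gain_phase_at(tr, ss_traj, k, axis)
            H = closed_form_frequency_response(
                p, "eq4_scalar_c", 2 * np.pi * k / T, axis="xy"[axis]
            )
            assert gain == pytest.approx(abs(H), rel=0.01)
            assert phase == pytest.approx(np.degrees(np.angle(H)), abs=1.0)

    def test_prediction_adds_low_frequency_lead_only(self):
        base = AVG_FIT_PARAMS.replace(c1=0.0, c2=0.0)
        pred = AVG_FIT_PARAMS.replace(c1=0.5, c2=0.5)
        w_low = 2 * np.pi * 0.2222
        ph = lambda p, w: np.degrees(
            np.angle(closed_form_frequency_response(p, "eq4_scalar_c", w))
        )
        lead_low = ph(pred, w_low) - ph(base, w_low)
        assert lead_low > 10.0  # substantial phase advance at the fundamental
        # the phase effect shrinks strongly with frequency
        w_hi = 2 * np.pi * 2.67
        lead_hi = ph(pred, w_hi) - ph(base, w_hi)
        assert 0 <= lead_hi < lead_low / 3

    def test_linearity_superposition(self, paths):
        from pursuitkit.trajectories import AxisSines, SumOfSinesSpec

        spec = paths[4]
        double = SumOfSinesSpec(
            spec.period,
            AxisSines(2 * spec.x.a1, spec.x.phi1, spec.x.k, 2 * spec.x.a2, spec.x.phi2),
            AxisSines(2 * spec.y.a1, spec.y.phi1, spec.y.k, 2 * spec.y.a2, spec.y.phi2),
        )
        p = AVG_FIT_PARAMS
        v1 = simulate_predictive_model(p, SumOfSinesTrajectory(spec), t_end=3.0).v
        v2 = simulate_predictive_model(p, SumOfSinesTrajectory(double), t_end=3.0).v
        assert np.allclose(v2, 2 * v1, rtol=1e-7, atol=1e-8)

    def test_steady_state_periodicity(self, ss_traj):
        tr = simulate_predictive_model(AVG_FIT_PARAMS, ss_traj, t_end=3 * T)
        n = int(T * 250)
        c1 = tr.v[n : 2 * n]
        c2 = tr.v[2 * n : 3 * n]
        rms = np.sqrt(np.mean(c1**2))
        assert np.sqrt(np.mean((c2 - c1) ** 2)) / rms < 1e-3

    def test_fast_path_matches_adaptive(self, ss_traj):
        p = AVG_FIT_PARAMS
        ref = simulate_predictive_model(p, ss_traj, t_end=5.7)
        v = fast_simulate_predictive(p, ss_traj, 5.7, 250.0)
        assert np.max(np.abs(v - ref.v)) / np.max(np.abs(ref.v)) < 1e-5


class TestPolarModel:
    def test_rectilinear_decoupled(self):
        # target moving at constant velocity along the initial eye direction
        traj = _ConstVel(10.0 * np.cos(0.5), 10.0 * np.sin(0.5))
        p = PursuitParams(a=6.0, d=6.0, g_x=0.7, g_y=0.7, c1=0.0, c2=0.0, tau=0.05)
        tr = simulate_polar_model(p, traj, t_end=4.0)
        theta = tr.meta["state"][:, 1]
        assert np.max(np.abs(theta - 0.5)) < 1e-6
        speed = tr.meta["state"][-1, 0]
        assert speed == pytest.approx(0.7 * 10.0, rel=1e-4)

    def test_direction_continuous_through_wrap(self, circle_spec):
        traj = SumOfSinesTrajectory(circle_spec)
        p = PursuitParams(a=7.0, d=8.0, g_x=0.9, g_y=0.9, c1=0.0, c2=0.0, tau=0.05)
        tr = simulate_polar_model(p, traj, t_end=2 * T)
        theta = tr.meta["state"][:, 1]
        assert np.max(np.abs(np.diff(theta))) < 0.1  # no 360 deg jumps

    @pytest.mark.parametrize("variant", ["standard", "directional_error"])
    def test_matches_fixed_step_euler_oracle(self, ss_traj, variant):
        """Brute-force Euler integration at dt = 1e-4 s as an independent
        check of the method-of-steps solution."""
        p = PursuitParams(a=6.0, d=6.0, g_x=0.6, g_y=0.5, c1=0.2, c2=0.2, tau=0.08)
        tr = simulate_polar_model(p, ss_traj, variant=variant, t_end=3.0)

        dt = 1e-4
        n = int(round(3.0 / dt))
        m = int(round(p.tau / dt))
        drive = predictive_drive(ss_traj, p)
        g = np.array([p.g_x, p.g_y])
        tgrid = dt * np.arange(n + 1)
        vp = g * ss_traj.velocity(tgrid - p.tau) + drive(tgrid - p.tau)
        theta_t = np.arctan2(vp[:, 1], vp[:, 0])
        v0 = ss_traj.velocity(0.0)
        y = np.zeros((n + 1, 2))
        y[0, 1] = np.arctan2(v0[1], v0[0])
        for i in range(n):
            lag = y[i - m] if i - m >= 0 else np.array([0.0, y[0, 1]])
            e_hat = np.array([np.cos(y[i, 1]), np.sin(y[i, 1])])
            dspeed = p.a * (e_hat @ vp[i] - lag[0])
            err = np.angle(np.exp(1j * (theta_t[i] - lag[1])))
            if y[i, 0] <= 0.5:
                dtheta = 0.0
            elif variant == "standard":
                dtheta = p.d * err
            else:
                dtheta = p.d * err / max(y[i, 0], 0.5)
            y[i + 1] = y[i] + dt * np.array([dspeed, dtheta])
        idx = (np.round(tr.t / dt)).astype(int)
        ve = y[idx, 0:1] * np.stack(
            [np.cos(y[idx, 1]), np.sin(y[idx, 1])], axis=-1
        )
        rms = np.sqrt(np.mean(ve**2))
        assert np.sqrt(np.mean((tr.v - ve) ** 2)) / rms < 0.005

    def test_invalid_variant_rejected(self, ss_traj):
        with pytest.raises(ValueError, match="variant"):
            simulate_polar_model(AVG_FIT_PARAMS, ss_traj, variant="cartesian")
        with pytest.raises(ValueError, match="speed_error"):
            simulate_polar_model(AVG_FIT_PARAMS, ss_traj, speed_error="angular")

    def test_speed_error_variants_agree_when_aligned(self):
        """For a rectilinear target aligned with the eye direction the
        projection and speed-difference error signals coincide."""
        traj = _ConstVel(10.0 * np.cos(0.5), 10.0 * np.sin(0.5))
        p = PursuitParams(a=6.0, d=6.0, g_x=0.7, g_y=0.7, c1=0.0, c2=0.0, tau=0.05)
        v1 = simulate_polar_model(p, traj, t_end=2.0, speed_error="projection").v
        v2 = simulate_polar_model(p, traj, t_end=2.0, speed_error="difference").v
        assert np.allclose(v1, v2, atol=1e-7)


class TestClosedForm:
    def test_dc_limit_is_gain(self):
        p = PursuitParams(a=6.0, g_x=0.8, tau_t=0.02, tau_e=0.12)
        H = closed_form_frequency_response(p, "eq1", 1e-9)
        assert abs(H) == pytest.approx(0.8, rel=1e-6)
        assert np.degrees(np.angle(H)) == pytest.approx(0.0, abs=1e-3)

    def test_first_order_pole(self):
        a = 6.0
        p = PursuitParams(a=a, g_x=0.8, c1=0.0, c2=0.0, tau=0.0)
        H = closed_form_frequency_response(p, "eq4_scalar_c", a)
        assert abs(H) == pytest.approx(0.8 / np.sqrt(2), rel=1e-9)
        assert np.degrees(np.angle(H)) == pytest.approx(-45.0, abs=1e-9)

    def test_average_parameters_give_low_frequency_lead(self):
        p = PursuitParams(a=7.12, b=3.47, g_x=0.53, c1=0.29, c2=0.29, tau=0.08)
        H = closed_form_frequency_response(p, "eq4_scalar_c", 2 * np.pi * 0.22)
        assert np.degrees(np.angle(H)) > 0

    def test_polar_model_rejected(self):
        with pytest.raises(ValueError, match="closed form|nonlinear"):
            closed_form_frequency_response(AVG_FIT_PARAMS, "polar", 1.0)

    def test_mismatched_c_rejected(self):
        p = PursuitParams(c1=0.3, c2=0.1)
        with pytest.raises(ValueError, match="c1 == c2"):
            closed_form_frequency_response(p, "eq4_scalar_c", 1.0)


def test_delay_consistency(ss_traj):
    """Shifting the target in time shifts the steady-state response by the
    same amount."""

    class _Shifted(TargetTrajectory):
        kind = "test"

        def __init__(self, base, delta):
            self.base, self.delta = base, delta
            self.period = base.period

        def position(self, t):
            return self.base.position(np.asarray(t) - self.delta)

        def velocity(self, t):
            return self.base.velocity(np.asarray(t) - self.delta)

        def acceleration(self, t):
            return self.base.acceleration(np.asarray(t) - self.delta)

    delta = 0.4
    p = AVG_FIT_PARAMS
    v_ref = simulate_predictive_model(p, ss_traj, t_end=3 * T)
    v_shift = simulate_predictive_model(p, _Shifted(ss_traj, delta), t_end=3 * T)
    # compare one steady-state cycle: shifted(t + delta) == ref(t)
    sel = (v_ref.t >= 2 * T) & (v_ref.t < 3 * T - delta - 0.01)
    i = np.flatnonzero(sel)
    j = i + int(round(delta * 250))
    scale = np.max(np.abs(v_ref.v))
    assert np.max(np.abs(v_shift.v[j] - v_ref.v[i])) / scale < 1e-4
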