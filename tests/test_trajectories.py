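"""Trajectory construction: sum-of-sines evaluation, constant-speed
reparameterization, axis mixing and the tangential/normal decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pursuitkit.trajectories import (
    AxisSines,
    SumOfSinesSpec,
    SumOfSinesTrajectory,
    combine_axes,
    default_paths,
    eval_sum_of_sines,
    load_specs,
    make_trajectory,
    reparameterize_constant_speed,
    save_specs,
    tangential_normal_acceleration,
)

T = 4.5
F0 = 1.0 / T


class TestSumOfSines:
    def test_zero_amplitudes_sit_at_offset(self):
        spec = SumOfSinesSpec(
            T,
            AxisSines(0, 0, 2, 0, 0, offset=3.0),
            AxisSines(0, 0, 3, 0, 0, offset=-1.5),
        )
        p, v, a = eval_sum_of_sines(spec, np.linspace(-5, 5, 11))
        assert np.allclose(p, [3.0, -1.5])
        assert np.allclose(v, 0) and np.allclose(a, 0)

    def test_single_sinusoid_peak_speed(self, single_axis_spec):
        t = np.linspace(0, T, 20001)
        _, v, _ = eval_sum_of_sines(single_axis_spec, t)
        peak = np.max(np.abs(v[:, 0]))
        assert peak == pytest.approx(2 * np.pi * 10.0 / T, rel=1e-6)

    def test_invalid_harmonic_order_rejected(self):
        with pytest.raises(ValueError, match="harmonic order"):
            AxisSines(10, 0, 4, 1, 0)

    def test_velocity_spectrum_has_power_only_at_its_harmonics(self, paths):
        # path 3 pairs the 3rd x-harmonic with the 2nd y-harmonic
        traj = SumOfSinesTrajectory(paths[3])
        t = np.linspace(0, T, 512, endpoint=False)
        amp = np.abs(np.fft.rfft(traj.velocity(t)[:, 0])) / 512
        hot = np.flatnonzero(amp > 1e-9 * amp.max())
        assert set(hot) == {1, 3}  # 0.22 and 0.67 Hz bins

    def test_derivatives_match_finite_differences(self, ss_traj):
        t = np.linspace(0.1, T, 200)
        h = 1e-5
        v_fd = (ss_traj.position(t + h) - ss_traj.position(t - h)) / (2 * h)
        a_fd = (ss_traj.velocity(t + h) - ss_traj.velocity(t - h)) / (2 * h)
        assert np.allclose(ss_traj.velocity(t), v_fd, atol=1e-5)
        assert np.allclose(ss_traj.acceleration(t), a_fd, atol=1e-4)


class TestConstantSpeed:
    def test_circle_is_invariant(self, circle_spec):
        cs = reparameterize_constant_speed(circle_spec)
        ss = SumOfSinesTrajectory(circle_spec)
        t = np.linspace(0, T, 300)
        assert np.allclose(cs.velocity(t), ss.velocity(t), atol=1e-3)

    @pytest.mark.parametrize("pid", [1, 2, 3, 4, 5])
    def test_speed_constant_within_tolerance(self, paths, pid):
        """|v| must equal arc_length / period to <= 1e-3 relative,
        with speed measured by an independent finite-difference oracle
        on a grid 10x finer than the construction grid."""
        cs = reparameterize_constant_speed(paths[pid])
        t = np.linspace(0, T, 40960, endpoint=False)
        h = T / 409600.0
        v_fd = (cs.position(t + h) - cs.position(t - h)) / (2 * h)
        speed = np.hypot(v_fd[:, 0], v_fd[:, 1])
        u = cs.arc_length / T
        assert np.max(np.abs(speed - u)) / u <= 1e-3
        assert cs.period == T

    def test_path_preserved(self, paths):
        """Discrete point-to-path distance between SS and CS paths, bounded
        by the reference polyline spacing (the oracle's own resolution)."""
        ss = SumOfSinesTrajectory(paths[2])
        cs = reparameterize_constant_speed(paths[2])
        t = np.linspace(0, T, 2000, endpoint=False)
        pss = ss.position(np.linspace(0, T, 20000, endpoint=False))
        pcs = cs.position(t)
        d = np.min(
            np.linalg.norm(pcs[:, None, :] - pss[None, :, :], axis=-1), axis=1
        )
        spacing = np.max(np.linalg.norm(np.diff(pss, axis=0), axis=-1))
        assert d.max() < spacing

    def test_cs_spectrum_richer_than_ss(self, paths):
        ss = SumOfSinesTrajectory(paths[2])
        cs = reparameterize_constant_speed(paths[2])
        t = np.linspace(0, T, 512, endpoint=False)
        a_ss = np.abs(np.fft.rfft(ss.velocity(t)[:, 0]))
        a_cs = np.abs(np.fft.rfft(cs.velocity(t)[:, 0]))
        ss_bins = set(np.flatnonzero(a_ss > 1e-6 * a_ss.max()))
        cs_bins = set(np.flatnonzero(a_cs > 1e-3 * a_cs.max()))
        assert cs_bins - ss_bins  # harmonics absent from the SS source

    def test_degenerate_path_rejected(self):
        spec = SumOfSinesSpec(T, AxisSines(0, 0, 2, 0, 0), AxisSines(0, 0, 2, 0, 0))
        with pytest.raises(ValueError, match="arc length"):
            reparameterize_constant_speed(spec)

    def test_near_cusp_warns(self):
        # rectilinear oscillation passes through speed zero
        spec = SumOfSinesSpec(
            T, AxisSines(10, 0, 2, 0, 0), AxisSines(0, 0, 2, 0, 0)
        )
        with pytest.warns(UserWarning, match="cusp"):
            reparameterize_constant_speed(spec)


class TestMixedAxes:
    def test_combining_with_itself_is_identity(self, ss_traj):
        mixed = combine_axes(ss_traj, ss_traj)
        t = np.linspace(-2, 7, 100)
        assert np.allclose(mixed.velocity(t), ss_traj.velocity(t))
        assert np.allclose(mixed.position(t), ss_traj.position(t))

    def test_x_velocity_comes_from_x_source_exactly(self, ss_traj, cs_traj):
        mixed = combine_axes(ss_traj, cs_traj)
        t = np.linspace(0, 2 * T, 500)
        assert np.array_equal(mixed.velocity(t)[:, 0], ss_traj.velocity(t)[:, 0])
        assert np.array_equal(mixed.velocity(t)[:, 1], cs_traj.velocity(t)[:, 1])

    def test_mixed_path_differs_from_source_path(self, ss_traj, cs_traj):
        mixed = combine_axes(ss_traj, cs_traj)
        t = np.linspace(0, T, 800, endpoint=False)
        pm = mixed.position(t)
        pss = ss_traj.position(np.linspace(0, T, 4000, endpoint=False))
        d = np.min(
            np.linalg.norm(pm[:, None, :] - pss[None, :, :], axis=-1), axis=1
        )
        assert d.max() > 0.1

    def test_mismatched_periods_rejected(self, ss_traj):
        other = SumOfSinesTrajectory(
            SumOfSinesSpec(3.0, AxisSines(5, 0, 2, 1, 0), AxisSines(5, 0, 2, 1, 0))
        )
        with pytest.raises(ValueError, match="period"):
            combine_axes(ss_traj, other)


class TestTangentialNormal:
    def test_uniform_circular_motion(self):
        w, r = 1.3, 8.0
        t = np.linspace(0, 4, 50)
        v = r * w * np.stack([-np.sin(w * t), np.cos(w * t)], axis=-1)
        a = -r * w * w * np.stack([np.cos(w * t), np.sin(w * t)], axis=-1)
        dec = tangential_normal_acceleration(v, a)
        assert np.allclose(dec.tangential, 0, atol=1e-9)
        assert np.allclose(np.abs(dec.normal), (r * w) * w)

    def test_rectilinear_motion(self):
        v = np.array([[3.0, 0.0]])
        a = np.array([[-2.0, 0.0]])
        dec = tangential_normal_acceleration(v, a)
        assert dec.normal[0] == pytest.approx(0.0)
        assert dec.tangential[0] == pytest.approx(-2.0)

    def test_reconstruction_and_speed_derivative(self, ss_traj):
        t = np.linspace(0, T, 1000, endpoint=False)
        v = ss_traj.velocity(t)
        a = ss_traj.acceleration(t)
        dec = tangential_normal_acceleration(v, a)
        recon = dec.tangential[:, None] * dec.t_hat + dec.normal[:, None] * dec.n_hat
        assert np.allclose(recon, a, atol=1e-9)
        # tangential component equals d|v|/dt (finite-difference oracle)
        h = 1e-4
        sp = lambda tt: np.hypot(*ss_traj.velocity(tt).T)
        dspeed = (sp(t + h) - sp(t - h)) / (2 * h)
        scale = np.max(np.abs(dspeed))
        assert np.max(np.abs(dec.tangential - dspeed)) / scale <= 1e-3

    def test_below_speed_floor_is_zero(self):
        dec = tangential_normal_acceleration([[0.1, 0.1]], [[5.0, 2.0]])
        assert dec.tangential[0] == 0.0 and dec.normal[0] == 0.0


class TestLibraryAndIO:
    def test_default_paths_satisfy_stimulus_constraints(self, paths):
        assert set(paths) == {1, 2, 3, 4, 5}
        for spec in paths.values():
            spec.validate(speed_bounds=(30.0, 40.0), window_halfwidth=15.0)
        assert paths[3].x.k == 3 and paths[3].y.k == 2

    @pytest.mark.parametrize("profile", ["ss", "cs", "ss-cs", "cs-ss"])
    def test_periodicity_all_kinds(self, paths, profile):
        traj = make_trajectory(paths[2], profile)
        t = np.linspace(0.0, T, 97)
        for attr in ("position", "velocity", "acceleration"):
            f = getattr(traj, attr)
            x0, x1 = f(t), f(t + T)
            scale = np.max(np.abs(x0)) + 1e-12
            assert np.max(np.abs(x1 - x0)) / scale < 1e-6, attr

    def test_spec_roundtrip(self, tmp_path, paths):
        f = tmp_path / "paths.yaml"
        save_specs(paths, f)
        loaded = load_specs(f)
        assert loaded == paths


@settings(max_examples=25, deadline=None)
@given(
    a1=st.floats(2.0, 12.0),
    phi1=st.floats(0.0, 6.28),
    a2=st.floats(0.5, 5.0),
    phi2=st.floats(0.0, 6.28),
    k=st.sampled_from([2, 3]),
)
def test_cs_speed_constancy_property(a1, phi1, a2, phi2, k):
    """Any non-degenerate two-harmonic path re-traverses at constant speed."""
    spec = SumOfSinesSpec(
        T,
        AxisSines(a1, phi1, k, a2, phi2),
        AxisSines(a1, phi1 + 1.2, k, a2, phi2 + 0.7),
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cs = reparameterize_constant_speed(spec)
    t = np.linspace(0, T, 2048, endpoint=False)
    v = cs.velocity(t)
    u = cs.arc_length / T
    assert np.max(np.abs(np.hypot(v[:, 0], v[:, 1]) - u)) / u < 1e-3
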