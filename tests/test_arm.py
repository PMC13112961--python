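"""Two-link arm model: kinematic identities and dynamic round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdnet.arm import (ArmParameters, JointState, ManipulandumParameters,
                       ReachabilityError, TorqueSample, coriolis_vector,
                       forward_kinematics, forward_simulate, inverse_dynamics,
                       inverse_kinematics, jacobian, mass_matrix)


def wrap(a):
    return (a + np.pi) % (2 * np.pi) - np.pi


class TestKinematics:
    @pytest.mark.parametrize("theta_s,theta_e,expected", [
        (0.0, -np.pi, ("l1+l2", 0.0)),      # collinear limbs
        (0.0, 0.0, ("l1-l2", 0.0)),         # fully folded
    ])
    def test_degenerate_postures(self, arm, theta_s, theta_e, expected):
        x, y = forward_kinematics(JointState(theta_s, theta_e), arm)
        ref = arm.l1 + arm.l2 if expected[0] == "l1+l2" else arm.l1 - arm.l2
        assert np.allclose([x, y], [ref, 0.0], atol=1e-12)

    def test_right_angle_elbow_posture(self, arm):
        # elbow at -pi/2 places the hand at distance sqrt(l1^2 + l2^2)
        x, y = forward_kinematics(JointState(-1.0031, -np.pi / 2), arm)
        assert x == pytest.approx(0.24551, abs=5e-5)
        assert y == pytest.approx(0.0, abs=5e-5)
        assert np.hypot(x, y) == pytest.approx(np.hypot(arm.l1, arm.l2), rel=1e-12)

    def test_ik_of_reach_boundary(self, arm):
        ts, te = inverse_kinematics(arm.l1 + arm.l2, 0.0, arm)
        assert ts == pytest.approx(0.0, abs=1e-9)
        assert te == pytest.approx(-np.pi, abs=1e-6)

    def test_ik_right_angle(self, arm):
        r = np.hypot(arm.l1, arm.l2)
        _, te = inverse_kinematics(r * np.cos(0.4), r * np.sin(0.4), arm)
        assert te == pytest.approx(-np.pi / 2, abs=1e-12)

    def test_ik_specific_point_round_trip(self, arm):
        ts, te = inverse_kinematics(0.2, 0.1, arm)
        assert -np.pi <= te <= 0.0
        x, y = forward_kinematics(JointState(ts, te), arm)
        assert np.allclose([x, y], [0.2, 0.1], atol=1e-12)

    def test_ik_fk_identity_grid(self, arm):
        # 1000-point grid over the convention range
        ts = np.linspace(-np.pi + 0.05, np.pi - 0.05, 40)
        te = np.linspace(-np.pi + 1e-4, -1e-4, 25)
        TS, TE = np.meshgrid(ts, te)
        x, y = forward_kinematics(JointState(TS, TE), arm)
        ts2, te2 = inverse_kinematics(x, y, arm)
        assert np.max(np.abs(wrap(ts2 - TS))) < 1e-9
        assert np.max(np.abs(te2 - TE)) < 1e-9

    def test_unreachable_raises(self, arm):
        with pytest.raises(ReachabilityError):
            inverse_kinematics(arm.l1 + arm.l2 + 0.01, 0.0, arm)
        with pytest.raises(ReachabilityError):
            inverse_kinematics(0.0, 0.5 * (arm.l2 - arm.l1), arm)


class TestJacobian:
    def test_entries_bounded_by_total_length(self, arm):
        rng = np.random.default_rng(0)
        st_ = JointState(rng.uniform(-np.pi, np.pi, 100),
                         rng.uniform(-np.pi, 0, 100))
        J = jacobian(st_, arm)
        assert np.all(np.abs(J) <= arm.l1 + arm.l2 + 1e-12)

    def test_matches_finite_difference(self, arm):
        ts, te, eps = 0.3, -1.2, 1e-6
        J = jacobian(JointState(ts, te), arm)
        for col, (dts, dte) in enumerate([(eps, 0.0), (0.0, eps)]):
            xp = forward_kinematics(JointState(ts + dts, te + dte), arm)
            xm = forward_kinematics(JointState(ts - dts, te - dte), arm)
            fd = (np.array(xp) - np.array(xm)) / (2 * eps)
            assert np.allclose(J[:, col], fd, atol=1e-6)

    def test_singular_at_full_extension(self, arm):
        J = jacobian(JointState(0.7, -np.pi), arm)
        assert np.linalg.det(J) == pytest.approx(0.0, abs=1e-12)


class TestDynamics:
    def test_mass_matrix_right_angle_entries(self, arm):
        M = mass_matrix(JointState(0.0, -np.pi / 2), arm)
        assert M[0, 1] == pytest.approx(arm.I2, abs=1e-15)
        assert M[0, 0] == pytest.approx(arm.I1 + arm.I2 + arm.m2 * arm.l1 ** 2, abs=1e-15)

    @given(st.floats(-np.pi + 1e-3, -1e-3))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_mass_matrix_symmetric_positive_definite(self, te):
        M = mass_matrix(JointState(0.0, te), ArmParameters())
        assert np.allclose(M, M.T)
        assert np.all(np.linalg.eigvalsh(M) > 0)

    def test_coriolis_zero_at_rest_and_at_sine_zeros(self, arm):
        assert np.allclose(coriolis_vector(JointState(0.2, -1.0, 0.0, 0.0), arm), 0)
        for te in (0.0, -np.pi):
            V = coriolis_vector(JointState(0.2, te, 3.0, -2.0), arm)
            assert np.allclose(V, 0, atol=1e-12)

    def test_energy_conserved_in_torque_free_motion(self, arm):
        # Coriolis/centrifugal terms do no net work on the arm alone
        dt, n = 1e-4, 5000
        zero = TorqueSample(np.zeros(n), np.zeros(n))
        init = JointState(0.4, -1.3, 1.5, -2.0)
        states = forward_simulate(zero, init, arm, manip=None, dt=dt)
        qd = np.stack([states.omega_s, states.omega_e], axis=1)
        M = mass_matrix(states, arm)
        E = 0.5 * np.einsum("ni,nij,nj->n", qd, M, qd)
        assert np.max(np.abs(E - E[0])) / E[0] < 1e-4

    def test_static_posture_needs_zero_torque(self, arm, manip):
        st_ = JointState(0.5, -1.0, 0.0, 0.0, 0.0, 0.0)
        tor = inverse_dynamics(st_, arm, manip)
        assert tor.tau_s == pytest.approx(0.0, abs=1e-15)
        assert tor.tau_e == pytest.approx(0.0, abs=1e-15)

    def test_zero_mass_manipulandum_degenerates(self, arm):
        st_ = JointState(np.r_[0.5, 0.4], np.r_[-1.0, -1.2],
                         np.r_[1.0, 0.5], np.r_[-0.5, 0.2],
                         np.r_[2.0, 1.0], np.r_[0.3, -0.4])
        plain = inverse_dynamics(st_, arm, None)
        degen = inverse_dynamics(st_, arm, ManipulandumParameters((0.0, 0.0)))
        assert np.allclose(plain.as_array(), degen.as_array())

    def test_torque_round_trip(self, arm, manip):
        # drive with a known torque profile, recover it from the motion
        n, dt = 15000, 1e-4
        t = np.arange(n) * dt
        tau = TorqueSample(0.05 * np.sin(2 * np.pi * 2 * t),
                           0.03 * np.cos(2 * np.pi * 3 * t))
        init = JointState(0.3, -1.5, 0.0, 0.0)
        states = forward_simulate(tau, init, arm, manip, dt=dt)
        rec = inverse_dynamics(states, arm, manip)
        rmse = np.sqrt(np.mean((rec.as_array() - tau.as_array()) ** 2))
        assert rmse < 1e-6

    def test_forward_simulation_self_convergence(self, arm):
        n, dt = 1000, 2e-4
        t = np.arange(n) * dt
        tau = TorqueSample(0.02 * np.sin(8 * t), 0.01 * np.cos(5 * t))
        init = JointState(0.3, -1.5, 0.0, 0.0)
        coarse = forward_simulate(tau, init, arm, dt=dt)
        t2 = np.arange(2 * n - 1) * dt / 2
        tau2 = TorqueSample(0.02 * np.sin(8 * t2), 0.01 * np.cos(5 * t2))
        fine = forward_simulate(tau2, init, arm, dt=dt / 2)
        assert abs(coarse.theta_s[-1] - fine.theta_s[-1]) < 1e-6
        assert abs(coarse.theta_e[-1] - fine.theta_e[-1]) < 1e-6

    def test_zero_torque_zero_velocity_stays_put(self, arm):
        tau = TorqueSample(np.zeros(100), np.zeros(100))
        states = forward_simulate(tau, JointState(0.3, -1.0, 0.0, 0.0), arm)
        assert np.allclose(states.theta_s, 0.3) and np.allclose(states.theta_e, -1.0)

    def test_scalar_and_length_one_series_agree(self, arm, manip):
        st1 = JointState(0.5, -1.0, 1.0, -0.5, 2.0, 0.3)
        stn = JointState(*[np.array([v]) for v in (0.5, -1.0, 1.0, -0.5, 2.0, 0.3)])
        t1 = inverse_dynamics(st1, arm, manip)
        tn = inverse_dynamics(stn, arm, manip)
        assert np.allclose(t1.as_array(), tn.as_array()[0])


class TestParameters:
    def test_defaults_use_rod_inertias(self):
        a = ArmParameters()
        assert a.I1 == pytest.approx(a.m1 * a.l1 ** 2 / 3)
        assert a.I2 == pytest.approx(a.m2 * a.l2 ** 2 / 3)
        assert a.lg2 == pytest.approx(a.l2 / 2)

    def test_validation(self):
        with pytest.raises(ValueError):
            ArmParameters(l1=-0.1)
        with pytest.raises(ValueError):
            ArmParameters(lg2=0.5)       # beyond forearm length
        with pytest.raises(ValueError):
            ManipulandumParameters((-1.0, 0.0))
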