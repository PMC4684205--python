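"""Articulated-dynamics oracles: inertia, conservation laws, stable PD."""

import numpy as np
import pytest

from plesioswim import body_dynamics as bd
from plesioswim import geometry as ge


def random_state(seed, pos_scale=1.0):
    rng = np.random.default_rng(seed)
    s = bd.BodyState(pos=rng.normal(scale=pos_scale, size=3),
                     theta=rng.uniform(-0.8, 0.8, 12))
    q = rng.normal(size=4)
    s.quat = q / np.linalg.norm(q)
    return s


class TestMassMatrix:
    def test_free_box_matches_closed_form_inertia(self, box_body):
        m = box_body.links["torso"].mass
        M = bd.mass_matrix(box_body, bd.BodyState())
        Ia = m / 12 * np.array([0.3**2 + 0.2**2, 0.4**2 + 0.2**2, 0.4**2 + 0.3**2])
        assert np.abs(np.diag(M)[:3] - m).max() < 1e-10
        assert np.abs(np.diag(M)[3:6] - Ia).max() < 1e-10
        off = M[:6, :6] - np.diag(np.diag(M))[:6, :6]
        assert np.abs(off).max() < 1e-10

    def test_symmetric_to_machine_precision(self, swimmer):
        for seed in range(5):
            M = bd.mass_matrix(swimmer, random_state(seed))
            assert np.abs(M - M.T).max() == 0.0

    def test_positive_definite_over_random_states(self, swimmer):
        for seed in range(100):
            M = bd.mass_matrix(swimmer, random_state(seed))
            assert np.linalg.eigvalsh(M).min() > 0

    def test_base_block_is_composite_mass(self, swimmer):
        M = bd.mass_matrix(swimmer, bd.BodyState())
        assert np.allclose(np.diag(M)[:3], swimmer.total_mass)


class TestBiasForces:
    def test_zero_velocity_gives_zero_bias(self, swimmer):
        s = random_state(3)
        assert np.abs(bd.bias_forces(swimmer, s)).max() < 1e-12

    def test_quadratic_scaling_in_velocity(self, swimmer):
        s = random_state(4)
        rng = np.random.default_rng(11)
        s.vel = rng.normal(size=3)
        s.omega = rng.normal(size=3)
        s.theta_dot = rng.normal(size=12)
        C1 = bd.bias_forces(swimmer, s)
        s2 = s.copy()
        s2.vel, s2.omega, s2.theta_dot = 2 * s.vel, 2 * s.omega, 2 * s.theta_dot
        C2 = bd.bias_forces(swimmer, s2)
        assert np.abs(C2 - 4 * C1).max() / np.abs(C2).max() < 1e-4

    def test_torque_free_spin_conserves_energy(self, box_body):
        # tumbling box, no external force: kinetic energy drift < 0.1% over 1 s
        m = box_body.links["torso"].mass
        I = box_body.links["torso"].inertia
        s = bd.BodyState(omega=np.array([1.0, 2.0, 0.5]))

        def ke(state):
            R = bd.quat_to_matrix(state.quat)
            return 0.5 * state.omega @ (R @ I @ R.T) @ state.omega

        e0 = ke(s)
        for _ in range(1000):
            s = bd.integrate(box_body, s, np.zeros(12), np.zeros(18), 1e-3)
        assert abs(ke(s) - e0) / e0 < 1e-3


class TestIntegrate:
    def test_rest_state_unchanged_without_forces(self, box_body):
        s0 = bd.BodyState(pos=np.array([1.0, 2.0, 3.0]))
        s1 = bd.integrate(box_body, s0, np.zeros(12), np.zeros(18), 0.01)
        assert np.allclose(s1.pos, s0.pos)
        assert np.allclose(s1.vel, 0) and np.allclose(s1.theta_dot, 0)

    def test_ballistic_displacement_under_constant_force(self, box_body):
        m = box_body.links["torso"].mass
        f, T, dt = 3.0, 1.0, 1e-3
        s = bd.BodyState()
        tau = np.zeros(18)
        tau[0] = f
        for _ in range(int(T / dt)):
            s = bd.integrate(box_body, s, np.zeros(12), tau, dt)
        expect = 0.5 * f / m * T**2
        assert s.pos[0] == pytest.approx(expect, rel=0.01)

    def test_flapping_in_vacuum_conserves_momentum(self, swimmer):
        # internal joint torques only: no self-propulsion without fluid
        s = bd.BodyState()
        dt = 1e-3
        for i in range(1000):
            t = i * dt
            tgt = 0.4 * np.sin(np.pi * t) * np.ones(12)
            tgtd = 0.4 * np.pi * np.cos(np.pi * t) * np.ones(12)
            tau = bd.spd_torques(swimmer, s, tgt, tgtd, dt)
            s = bd.integrate(swimmer, s, tau, np.zeros(18), dt)
        kin = bd.kinematic_cache(swimmer, s)
        mom = sum(swimmer.links[n].mass * (kin.Jv[n] @ s.qdot)
                  for n in bd.LINK_NAMES)
        # linear momentum per unit mass stays ~0 (integration tolerance)
        assert np.abs(mom).max() / swimmer.total_mass < 1e-3

    def test_nan_acceleration_aborts(self, box_body):
        s = bd.BodyState()
        tau = np.full(18, np.nan)
        with pytest.raises(FloatingPointError):
            bd.integrate(box_body, s, np.zeros(12), tau, 0.01)


class TestStablePD:
    def test_zero_torque_at_target(self, swimmer):
        s = bd.BodyState(theta=np.full(12, 0.3), theta_dot=np.full(12, 0.2))
        tgt = s.theta + 0.01 * s.theta_dot
        tau = bd.spd_torques(swimmer, s, tgt, s.theta_dot, 0.01)
        assert np.abs(tau).max() < 1e-10

    def test_torque_linear_in_position_error(self, swimmer):
        s = bd.BodyState()
        t1 = bd.spd_torques(swimmer, s, np.full(12, 0.1), np.zeros(12), 0.01)
        t2 = bd.spd_torques(swimmer, s, np.full(12, 0.2), np.zeros(12), 0.01)
        assert np.allclose(2 * t1, t2)

    def test_step_target_settles_without_divergence(self, swimmer):
        # at these gains and dt the explicit damping law diverges
        # (k_d * dt exceeds the rotation DOF inertia); stable PD settles
        dt = 0.01
        s = bd.BodyState()
        tgt = np.zeros(12)
        tgt[2] = 0.5  # low-inertia rotation DOF
        for _ in range(100):
            tau = bd.spd_torques(swimmer, s, tgt, np.zeros(12), dt)
            s = bd.integrate(swimmer, s, tau, np.zeros(18), dt)
        assert np.all(np.isfinite(s.theta))
        assert abs(s.theta[2] - 0.5) < 0.02 * 0.5

    def test_explicit_damping_diverges_at_same_gains(self, swimmer):
        dt = 0.01
        s = bd.BodyState()
        tgt = np.zeros(12)
        tgt[2] = 0.5
        diverged = False
        for _ in range(100):
            tau = bd.spd_torques(swimmer, s, tgt, np.zeros(12), dt)
            try:
                s = bd.integrate(swimmer, s, tau, np.zeros(18), dt,
                                 implicit_damping=False)
            except FloatingPointError:
                diverged = True
                break
        diverged = diverged or not np.all(np.isfinite(s.theta)) \
            or np.abs(s.theta[2]) > 10
        assert diverged


class TestInterfaceKinematics:
    def test_zero_velocity_gives_zero_surface_velocity(self, swimmer):
        s = random_state(5)
        kin = bd.kinematic_cache(swimmer, s)
        pt = kin.pivot_w["hind_right"] + np.array([0.05, -0.3, 0.0])
        J, jdqd, v = bd.interface_kinematics(swimmer, s, pt, "hind_right", kin)
        assert np.allclose(v, 0) and np.allclose(jdqd, 0)

    def test_pure_base_translation(self, swimmer):
        s = bd.BodyState(vel=np.array([0.7, -0.2, 0.1]))
        kin = bd.kinematic_cache(swimmer, s)
        for name in ("torso", "fore_left"):
            pts = kin.link_com[name][None, :] + np.array([[0.1, 0.2, -0.1]])
            ids = np.array([bd._LINK_INDEX[name]])
            v = bd.point_velocities(swimmer, s, pts, ids, kin)
            assert np.allclose(v[0], s.vel)

    def test_single_revolute_rate_times_radius(self, swimmer):
        s = bd.BodyState()
        s.theta_dot[0] = 1.3  # fore-left dorsoventral
        kin = bd.kinematic_cache(swimmer, s)
        axis = kin.axes_w["fore_left"][0]
        r_vec = np.array([0.0, 0.6, 0.0])  # along the span from the pivot
        pt = kin.pivot_w["fore_left"] + r_vec
        _, _, v = bd.interface_kinematics(swimmer, s, pt, "fore_left", kin)
        r_perp = np.linalg.norm(r_vec - (r_vec @ axis) * axis)
        assert np.linalg.norm(v) == pytest.approx(1.3 * r_perp, rel=1e-9)

    def test_jacobian_matches_finite_differences(self, swimmer):
        s = random_state(6)
        kin = bd.kinematic_cache(swimmer, s)
        name = "fore_left"
        loc = np.array([0.1, 0.5, 0.0])
        pt = kin.pivot_w[name] + kin.link_R[name] @ loc
        J, _, _ = bd.interface_kinematics(swimmer, s, pt, name, kin)
        eps = 1e-6
        for i in range(3):  # this link's joint DOFs
            sp, sm = s.copy(), s.copy()
            sp.theta = s.theta.copy(); sp.theta[i] += eps
            sm.theta = s.theta.copy(); sm.theta[i] -= eps
            kp, km = bd.kinematic_cache(swimmer, sp), bd.kinematic_cache(swimmer, sm)
            fd = ((kp.pivot_w[name] + kp.link_R[name] @ loc)
                  - (km.pivot_w[name] + km.link_R[name] @ loc)) / (2 * eps)
            assert np.abs(fd - J[:, 6 + i]).max() < 1e-5

    def test_unknown_link_rejected(self, swimmer):
        with pytest.raises(KeyError):
            bd.interface_kinematics(swimmer, bd.BodyState(), np.zeros(3), "tail")

    def test_jdot_qdot_matches_analytic_centripetal(self, swimmer):
        # steady rotation about one joint axis: J̇q̇ = ω x (ω x r)
        s = bd.BodyState()
        s.theta_dot[1] = 0.9  # fore-left anteroposterior
        kin = bd.kinematic_cache(swimmer, s)
        axis = kin.axes_w["fore_left"][1]
        omega = 0.9 * axis
        r = np.array([0.0, 0.55, 0.0])
        pt = kin.pivot_w["fore_left"] + r
        _, jdqd, _ = bd.interface_kinematics(swimmer, s, pt, "fore_left", kin)
        expect = np.cross(omega, np.cross(omega, r))
        assert np.abs(jdqd - expect).max() < 1e-4
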