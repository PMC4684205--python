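"""Two-way coupling: statics, consistency and reduction properties."""

import numpy as np
import pytest

from plesioswim import body_dynamics as bd
from plesioswim import coupling as cp
from plesioswim import fluid_grid as fg
from plesioswim import geometry as ge
from tests.conftest import make_single_link_body


def submerged_setup(body, n=24, L=3.0, pos=None):
    g = fg.MacGrid(shape=(n, n, n), dx=L / n)
    state = bd.BodyState(pos=np.asarray(pos if pos is not None else [L/2, L/2, L/2]))
    kin = bd.KinCache(body, state)
    vox = cp.revoxelize(body, state, g, kin)
    g.owner = vox.owner
    return g, state, kin, vox


class TestPressureForce:
    def test_zero_pressure_gives_zero_force(self, sphere_body):
        g, state, kin, vox = submerged_setup(sphere_body)
        imap = cp.build_interface_map(sphere_body, state, g, vox, kin, with_jdot=False)
        tau = cp.pressure_to_generalized_force(np.zeros(g.shape), imap)
        assert np.allclose(tau, 0)

    def test_uniform_pressure_on_closed_body_nets_to_zero(self, sphere_body):
        g, state, kin, vox = submerged_setup(sphere_body, n=32)
        imap = cp.build_interface_map(sphere_body, state, g, vox, kin, with_jdot=False)
        c = 5000.0
        p = np.where(~g.solid, c, 0.0)
        tau = cp.pressure_to_generalized_force(p, imap)
        A = np.pi * 0.45**2
        assert np.abs(tau[:3]).max() <= 0.02 * c * A

    def test_hydrostatic_pressure_recovers_archimedes(self, sphere_body, sphere_mesh):
        g, state, kin, vox = submerged_setup(sphere_body, n=32)
        imap = cp.build_interface_map(sphere_body, state, g, vox, kin, with_jdot=False)
        tau = cp.pressure_to_generalized_force(cp.hydrostatic_field(g), imap)
        buoyancy = 1000 * 9.81 * sphere_mesh.volume
        assert tau[2] == pytest.approx(buoyancy, rel=0.05)
        assert abs(tau[0]) < 0.01 * buoyancy and abs(tau[1]) < 0.01 * buoyancy

    def test_stale_interface_map_rejected(self, sphere_body):
        g, state, kin, vox = submerged_setup(sphere_body)
        imap = cp.build_interface_map(sphere_body, state, g, vox, kin, with_jdot=False)
        with pytest.raises(ValueError, match="stale"):
            cp.pressure_to_generalized_force(np.zeros(g.shape), imap,
                                             expected_time=state.t + 0.01)


class TestCoupledSystem:
    def test_reduces_to_pure_fluid_poisson_without_solid(self, box_body):
        g = fg.MacGrid(shape=(12, 12, 12), dx=0.25)
        state = bd.BodyState(pos=np.array([1.5, 1.5, 1.5]))
        # voxelize an empty mesh list: all cells stay fluid
        vox = ge.voxelize([], g.origin, g.dx, g.shape)
        g.solid, g.frac = vox.solid, vox.frac
        solver = fg.PressureSolver(g)
        sysm = cp.assemble_coupled_system(box_body, state, g, vox,
                                          np.zeros(18), 0.01, solver)
        A_pure = solver.laplacian(0.01, np.ones(g.shape, bool))
        rng = np.random.default_rng(0)
        for _ in range(3):
            x = rng.normal(size=g.n_cells)
            assert np.allclose(sysm.matvec(x), A_pure @ x)

    def test_matrix_symmetric_and_psd(self, sphere_body):
        g, state, kin, vox = submerged_setup(sphere_body, n=16)
        solver = fg.PressureSolver(g)
        sysm = cp.assemble_coupled_system(sphere_body, state, g, vox,
                                          np.zeros(18), 0.01, solver, kin)
        rng = np.random.default_rng(1)
        norm_est = 0.0
        for _ in range(5):
            x = rng.normal(size=g.n_cells)
            y = rng.normal(size=g.n_cells)
            Ax, Ay = sysm.matvec(x), sysm.matvec(y)
            assert y @ Ax == pytest.approx(x @ Ay, rel=1e-9, abs=1e-12)
            norm_est = max(norm_est, np.linalg.norm(Ax) / np.linalg.norm(x))
            assert x @ Ax >= -1e-10 * norm_est * (x @ x)

    def test_action_reaction_shares_face_data(self, sphere_body):
        # the assembled solid block and the force map use the same H
        g, state, kin, vox = submerged_setup(sphere_body, n=16)
        solver = fg.PressureSolver(g)
        sysm = cp.assemble_coupled_system(sphere_body, state, g, vox,
                                          np.zeros(18), 0.01, solver, kin)
        rng = np.random.default_rng(2)
        p = rng.normal(size=g.n_cells)
        tau = cp.pressure_to_generalized_force(p.reshape(g.shape), sysm.imap)
        assert np.allclose(tau, sysm.imap.H.T @ p)
        # solid part of the matvec is exactly H M^-1 H^T (scaled)
        solid_part = sysm.matvec(p) - sysm.A_fluid @ p
        expect = (0.01 / g.dx**3) * (sysm.imap.H @ bd.mass_solve(sysm.Minv_factor, tau))
        assert np.allclose(solid_part, expect)

    def test_immovable_solid_acts_as_fixed_obstacle(self, sphere_mesh):
        # M -> infinity removes the solid response: flow projects around a
        # fixed body and the body receives no velocity change
        mesh = sphere_mesh
        m, com, I = mesh.mass_properties()
        heavy = bd.RigidLink("torso", mesh, m * 1e12, com, I * 1e12)
        body = bd.ArticulatedBody(spec=None, links={"torso": heavy}, joints={})
        g, state, kin, vox = submerged_setup(body, n=16)
        g.g[:] = 0.0
        rng = np.random.default_rng(3)
        for a in range(3):
            g.u[a][:] = 0.1 * rng.normal(size=g.u[a].shape)
        solver = fg.PressureSolver(g)
        state2, diag = cp.coupled_step(body, state, g, np.zeros(12), np.zeros(12),
                                       0.01, solver, gravity_on=False)
        assert np.linalg.norm(state2.vel) < 1e-8
        assert diag.max_div < 1e-5


class TestCoupledStep:
    def test_neutrally_buoyant_sphere_rests(self, sphere_body):
        # short-horizon equilibrium; the full 2 s rest run lives in the
        # acceptance tests
        g, state, kin, vox = submerged_setup(sphere_body, n=16)
        solver = fg.PressureSolver(g)
        p0 = state.pos.copy()
        for _ in range(25):
            state, diag = cp.coupled_step(sphere_body, state, g,
                                          np.zeros(12), np.zeros(12), 0.01, solver)
        assert np.linalg.norm(state.pos - p0) < 1e-6

    def test_static_body_in_still_water_stays(self, swimmer, presets):
        from plesioswim.swim import SimConfig, initial_state
        cfg = SimConfig(grid="25x20x15")
        grid = cfg.make_grid()
        solver = fg.PressureSolver(grid)
        state = initial_state(swimmer, presets["medium"], "all", cfg.start_pos)
        tgt = state.theta.copy()
        p0 = state.pos.copy()
        for _ in range(20):
            state, _ = cp.coupled_step(swimmer, state, grid, tgt,
                                       np.zeros(12), 0.02, solver)
        assert np.linalg.norm(state.vel) < 1e-3
        assert np.linalg.norm(state.pos - p0) < 1e-4

    def test_towed_box_drives_interface_fluid(self):
        # box moving at constant velocity: nearby fluid follows it
        box = make_single_link_body(ge.box_mesh((0.6, 0.6, 0.6)))
        g, state, kin, vox = submerged_setup(box, n=24)
        g.g[:] = 0.0
        solver = fg.PressureSolver(g)
        v_tow = np.array([0.5, 0.0, 0.0])
        for _ in range(10):
            state.vel = v_tow.copy()  # re-impose the tow each step
            state, _ = cp.coupled_step(box, state, g, np.zeros(12),
                                       np.zeros(12), 0.01, solver,
                                       gravity_on=False)
        # fraction-weighted mean normal fluid velocity at coupled x-faces
        imap_vox = cp.revoxelize(box, state, g)
        imap = cp.build_interface_map(box, state, g, imap_vox, with_jdot=False)
        mx = imap.axis == 0
        # fluid velocity sampled at face centers
        vels = fg.sample_velocity(g, imap.centers[mx])[:, 0]
        w = imap.weight[mx]
        mean_v = np.sum(w * vels) / np.sum(w)
        assert mean_v == pytest.approx(v_tow[0], rel=0.05)

    @staticmethod
    def _impulsive_start(sphere_body, subres):
        """One coupled step of a sphere started at 0.4 m/s in still water."""
        g, state, kin, vox = submerged_setup(sphere_body, n=24)
        g.g[:] = 0.0
        solver = fg.PressureSolver(g)
        state.vel = np.array([0.4, 0.0, 0.0])
        state2, _ = cp.coupled_step(sphere_body, state, g, np.zeros(12),
                                    np.zeros(12), 0.01, solver,
                                    gravity_on=False, subres=subres)
        return g, state2

    def test_added_mass_of_impulsively_started_sphere(self, sphere_body):
        # inviscid impulsive start: momentum is shared with the added mass
        # m/2 of a sphere, so the velocity drops to 2/3 of the initial value
        g, state2 = self._impulsive_start(sphere_body, subres=3)
        assert state2.vel[0] == pytest.approx(0.4 * 2 / 3, rel=0.05)
        assert abs(state2.vel[1]) < 1e-6 and abs(state2.vel[2]) < 1e-6

    def test_subgrid_fractions_improve_interface_flow(self, sphere_body):
        # after the impulsive start the flow is potential; compare the
        # velocity on a shell one cell outside the surface with the analytic
        # dipole of a translating sphere; 3x3x3 fractions must not be worse
        # than binary voxelization
        R = 0.45
        rng = np.random.default_rng(0)
        dirs = rng.normal(size=(400, 3))
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        errs = {}
        for subres in (1, 3):
            g, state2 = self._impulsive_start(sphere_body, subres)
            rr = R + g.dx
            pts = np.array([1.5, 1.5, 1.5]) + rr * dirs
            v = fg.sample_velocity(g, pts)
            Ub = state2.vel
            van = (R**3 / (2 * rr**3)) * (3 * (dirs @ Ub)[:, None] * dirs - Ub)
            errs[subres] = np.sqrt(np.mean(np.sum((v - van) ** 2, axis=1)))
        assert errs[3] <= errs[1]
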