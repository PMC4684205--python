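"""Trajectory quality, traces, and simulation orchestration (cheap grids)."""

import numpy as np
import pytest

from plesioswim import body_dynamics as bd
from plesioswim import stroke as st
from plesioswim import swim as sw


def straight_trajectory(distance_per_cycle=0.92, heading=None, n_cycles=2,
                        hz=st.STROKE_FREQUENCY_HZ):
    """Synthetic uniform-speed trajectory along a given heading."""
    heading = np.array([1.0, 0, 0]) if heading is None else np.asarray(heading, float)
    heading = heading / np.linalg.norm(heading)
    n = 41
    t = np.linspace(0, n_cycles / hz, n)
    com = np.outer(t * distance_per_cycle * hz, heading)
    quat = np.tile([1.0, 0, 0, 0], (n, 1))
    lateral = np.array([-heading[1], heading[0], 0.0])
    if np.linalg.norm(lateral) < 1e-12:
        lateral = np.array([0.0, 1.0, 0.0])
    lateral /= np.linalg.norm(lateral)
    up = np.cross(heading, lateral)
    return sw.Trajectory(t=t, com=com, base_pos=com.copy(), base_quat=quat,
                         theta=np.zeros((n, 12)), torque=np.zeros((n, 12)),
                         heading0=heading, up0=up, lateral0=lateral)


class TestQuality:
    def test_published_distance_maps_to_speed(self):
        # 0.92 m per cycle at 0.5 Hz -> 0.46 m/s mean speed, zero deviation
        q = sw.quality(straight_trajectory(0.92))
        assert q.forward_distance == pytest.approx(0.92, abs=1e-9)
        assert q.mean_speed == pytest.approx(0.46, abs=1e-9)
        assert q.lateral_deviation == pytest.approx(0.0, abs=1e-12)
        assert q.vertical_deviation == pytest.approx(0.0, abs=1e-12)
        assert q.orientation_deviation == pytest.approx(0.0, abs=1e-9)

    def test_pure_sideways_motion_scores_negative(self):
        traj = straight_trajectory(0.5)
        # rotate the displacement to be perpendicular to the stored heading
        traj.com = np.outer(traj.t * 0.25, np.array([0.0, 1.0, 0.0]))
        q = sw.quality(traj)
        assert q.forward_distance == pytest.approx(0.0, abs=1e-12)
        assert q.quality < 0

    def test_frame_invariance(self):
        qa = sw.quality(straight_trajectory(0.7, heading=[1, 0, 0]))
        qb = sw.quality(straight_trajectory(0.7, heading=[0.6, 0.8, 0.0]))
        for field in ("forward_distance", "lateral_deviation",
                      "vertical_deviation", "mean_speed", "quality"):
            assert getattr(qa, field) == pytest.approx(getattr(qb, field), abs=1e-9)

    def test_quality_decreases_with_deviation(self):
        base = sw.quality(straight_trajectory(0.8)).quality
        traj = straight_trajectory(0.8)
        traj.com = traj.com + np.outer(traj.t, [0.0, 0.05, 0.0])
        assert sw.quality(traj).quality < base

    def test_too_short_trajectory_rejected(self):
        traj = straight_trajectory(0.5, n_cycles=1)
        with pytest.raises(ValueError):
            sw.quality(traj)


class TestTipTraces:
    def test_static_limbs_give_single_point(self, swimmer):
        n = 11
        t = np.linspace(0, 4, n)
        traj = sw.Trajectory(t=t, com=np.zeros((n, 3)),
                             base_pos=np.zeros((n, 3)),
                             base_quat=np.tile([1.0, 0, 0, 0], (n, 1)),
                             theta=np.zeros((n, 12)), torque=np.zeros((n, 12)),
                             heading0=np.array([1.0, 0, 0]),
                             up0=np.array([0.0, 0, 1]),
                             lateral0=np.array([0.0, 1, 0]))
        traces = sw.tip_traces(traj, swimmer)
        for path in traces.values():
            assert np.abs(path - path[0]).max() < 1e-12

    def test_dorsoventral_flap_is_planar_arc(self, swimmer):
        # pure dv rotation about the anterior axis: tip stays in a plane
        n = 41
        t = np.linspace(0, 4, n)
        theta = np.zeros((n, 12))
        theta[:, 0] = 0.5 * np.sin(np.pi * t)  # fore-left dv only
        traj = sw.Trajectory(t=t, com=np.zeros((n, 3)),
                             base_pos=np.zeros((n, 3)),
                             base_quat=np.tile([1.0, 0, 0, 0], (n, 1)),
                             theta=theta, torque=np.zeros((n, 12)),
                             heading0=np.array([1.0, 0, 0]),
                             up0=np.array([0.0, 0, 1]),
                             lateral0=np.array([0.0, 1, 0]))
        path = sw.tip_traces(traj, swimmer)["fore_left"]
        # rotation about the x axis: the x coordinate never changes and the
        # tip stays at a constant radius from the pivot (a transverse arc)
        assert np.abs(path[:, 0] - path[0, 0]).max() < 1e-9
        pivot = swimmer.joints["fore_left"].pivot
        r = np.linalg.norm(path[:, 1:] - pivot[1:], axis=1)
        assert r.std() / r.mean() < 1e-9


class TestParticleTraces:
    def test_infinite_threshold_gives_empty_set(self):
        from plesioswim.fluid_grid import MacGrid
        g = MacGrid(shape=(8, 8, 8), dx=0.1)
        snaps = [(0.0, g.copy_velocity()), (0.1, g.copy_velocity())]
        assert sw.particle_traces(g, snaps, vorticity_threshold=np.inf) == []

    def test_rotating_flow_produces_traces(self):
        from plesioswim.fluid_grid import MacGrid
        g = MacGrid(shape=(12, 12, 12), dx=0.1)
        # rigid rotation about z: vorticity = 2*omega = 10 > 1.5
        X = g.face_positions(0)
        g.u[0] = -5.0 * (X[..., 1] - 0.6)
        Y = g.face_positions(1)
        g.u[1] = 5.0 * (Y[..., 0] - 0.6)
        snaps = [(0.0, g.copy_velocity()), (0.05, g.copy_velocity())]
        traces = sw.particle_traces(g, snaps, n_particles=100, seed=1)
        assert len(traces) > 50


class TestRunSimulation:
    CHEAP = sw.SimConfig(grid="25x20x15", dt=0.02, n_cycles=2.0, record_every=2)

    def test_zero_amplitude_stroke_produces_no_thrust(self, swimmer, presets):
        preset = presets["medium"]
        dv, ap, rot = st.neutral_pose(preset, "fore")
        fore = st.LimbStroke(st.SinusoidSpec(dv, dv, 0.0), st.SinusoidSpec(ap, ap, 0.0),
                             st.SinusoidSpec(rot, rot, 0.0), 0.0)
        dv, ap, rot = st.neutral_pose(preset, "hind")
        hind = st.LimbStroke(st.SinusoidSpec(dv, dv, 0.0), st.SinusoidSpec(ap, ap, 0.0),
                             st.SinusoidSpec(rot, rot, 0.0), 0.0)
        params = st.StrokeParams(fore=fore, hind=hind)
        traj = sw.run_simulation(swimmer, params, preset, "all", self.CHEAP)
        assert traj.completed
        q = sw.quality(traj)
        assert abs(q.forward_distance) < 0.02

    def test_trajectory_sampling_matches_config(self, swimmer, presets):
        cfg = sw.SimConfig(grid="25x20x15", dt=0.02, n_cycles=2.0, record_every=5)
        params = sw.reference_stroke("medium", "fore")
        traj = sw.run_simulation(swimmer, params, presets["medium"], "fore", cfg)
        n_steps = int(round(cfg.n_cycles / params.frequency / cfg.dt))
        assert len(traj.t) == n_steps // cfg.record_every + 1
        assert np.allclose(np.diff(traj.t), cfg.dt * cfg.record_every)
        assert traj.t[-1] == pytest.approx(cfg.n_cycles / params.frequency)

    def test_gait_phase_diagnostic_recovers_encoded_offset(self):
        # cross-correlation lag between fore and hind dv target signals
        # recovers the encoded phase offset
        params = sw.reference_stroke("medium", "all")
        from dataclasses import replace
        hind = params.hind
        offset = 0.3
        hind = st.LimbStroke(replace(hind.dorsoventral, phase=(params.fore.dorsoventral.phase + offset) % 1),
                             hind.anteroposterior, hind.rotation, hind.rotation_hold)
        p2 = st.StrokeParams(fore=params.fore, hind=hind)
        t = np.arange(0, 8, 0.005)
        jt = st.joint_targets(p2, t, "all", st.load_presets()["medium"])
        fore_dv = jt[:, 0] - jt[:, 0].mean()
        hind_dv = jt[:, 6] - jt[:, 6].mean()
        period_samples = int(round(2.0 / 0.005))
        lags = np.arange(period_samples)
        # hind(t - lag) aligns with fore(t) at lag = offset * period
        cc = [np.dot(fore_dv, np.roll(hind_dv, lag)) for lag in lags]
        best = lags[int(np.argmax(cc))] / period_samples
        assert best == pytest.approx(offset, abs=0.02)


def test_trajectory_csv_roundtrip(tmp_path):
    traj = straight_trajectory(0.5)
    path = tmp_path / "traj.csv"
    traj.to_csv(str(path))
    import pandas as pd
    df = pd.read_csv(path)
    assert len(df) == len(traj.t)
    assert df["com_x"].iloc[-1] == pytest.approx(traj.com[-1, 0])
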