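"""Full swimming-simulation orchestration and the straight-swimming quality.

A simulation places the swimmer in a box of water (default desk-scale grid
50x40x30 at Δx = 0.132 m over a 6.6 x 5.28 x 3.96 m domain; the full-scale
100x80x60 grid is a config switch), starts body and water at rest with the
active limbs fully abducted and inactive limbs locked at neutral, and runs
the two-way coupled stepper for at least two stroke cycles.

The straight-swimming quality of a trajectory is evaluated over the second
cycle only (the first covers the start-up transient):

``q = d_forward − w_dir·‖d_perp‖ − w_orient·|Δorientation|``

with ``d_forward`` the displacement of the swimmer's center of mass
projected on its initial heading, ``d_perp`` the perpendicular COM
displacement, and ``Δorientation`` the geodesic body-orientation change
over the cycle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from . import body_dynamics as bd
from . import stroke as st
from .body_dynamics import ArticulatedBody, BodyState, KinCache
from .coupling import coupled_step
from .fluid_grid import MacGrid, PressureSolver
from .geometry import BodySpec, build_swimmer

__all__ = [
    "SimConfig",
    "Trajectory",
    "QualityResult",
    "initial_state",
    "run_simulation",
    "quality",
    "tip_traces",
    "particle_traces",
    "reference_stroke",
]


@dataclass
class SimConfig:
    """Simulation configuration.

    ``grid`` picks the resolution over the fixed water domain: ``desk``
    (50x40x30, Δx 0.132 m) for workstation runs or ``paper`` (100x80x60,
    Δx 0.066 m) for full-scale runs.  ``n_cycles`` counts 2 s stroke
    cycles; quality needs at least two.
    """

    grid: str = "desk"
    domain: tuple = (6.6, 5.28, 3.96)
    dt: float = 0.01
    n_cycles: float = 2.0
    record_every: int = 5
    gravity_on: bool = True
    subres: int = 3
    start_pos: tuple = (2.3, 2.64, 1.85)
    w_dir: float = 1.0       # m penalty per m of perpendicular deviation
    w_orient: float = 0.5    # m penalty per rad of orientation change
    snapshot_every: int = 0  # velocity-field snapshots (0 = off)

    def grid_shape(self) -> tuple:
        named = {"desk": (50, 40, 30), "paper": (100, 80, 60)}
        if self.grid in named:
            return named[self.grid]
        return tuple(int(v) for v in self.grid.split("x"))

    def make_grid(self) -> MacGrid:
        shape = self.grid_shape()
        dx = self.domain[0] / shape[0]
        return MacGrid(shape=shape, dx=dx)


@dataclass
class Trajectory:
    """Uniformly sampled record of a swimming simulation."""

    t: np.ndarray
    com: np.ndarray          # (n,3) whole-body center of mass
    base_pos: np.ndarray
    base_quat: np.ndarray
    theta: np.ndarray        # (n,12) joint angles, rad
    torque: np.ndarray       # (n,12) internal joint torques
    heading0: np.ndarray     # initial heading unit vector
    up0: np.ndarray
    lateral0: np.ndarray
    frequency: float = st.STROKE_FREQUENCY_HZ
    completed: bool = True
    snapshots: list = field(default_factory=list)
    diagnostics: list = field(default_factory=list)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def to_csv(self, path) -> None:
        cols = {"t": self.t}
        for i, n in enumerate("xyz"):
            cols[f"com_{n}"] = self.com[:, i]
            cols[f"base_{n}"] = self.base_pos[:, i]
        for i, n in enumerate("wxyz"):
            cols[f"quat_{n}"] = self.base_quat[:, i]
        for j in range(12):
            cols[f"theta_{j}"] = self.theta[:, j]
        pd.DataFrame(cols).to_csv(path, index=False)


@dataclass
class QualityResult:
    forward_distance: float
    lateral_deviation: float
    vertical_deviation: float
    orientation_deviation: float
    mean_speed: float
    quality: float

    def to_json(self, path=None):
        d = {k: float(v) for k, v in self.__dict__.items()}
        if path is not None:
            with open(path, "w") as fh:
                json.dump(d, fh, indent=2)
        return d


def _body_com(body: ArticulatedBody, kin: KinCache) -> np.ndarray:
    m = 0.0
    c = np.zeros(3)
    for name in bd.LINK_NAMES:
        link = body.links[name]
        c += link.mass * kin.link_com[name]
        m += link.mass
    return c / m


def initial_state(body: ArticulatedBody, preset: st.JointRangePreset,
                  active_limbs: str, start_pos) -> BodyState:
    """Rest state: active limbs fully abducted, inactive at neutral."""
    theta = np.zeros(12)
    for j, (pair, _side) in enumerate(st.JOINT_ORDER):
        active = active_limbs == "all" or active_limbs == pair
        pose = st.abducted_pose(preset, pair) if active else st.neutral_pose(preset, pair)
        theta[3 * j: 3 * j + 3] = np.deg2rad(pose)
    return BodyState(pos=np.asarray(start_pos, float), theta=theta)


def run_simulation(body: ArticulatedBody, params: st.StrokeParams,
                   preset: st.JointRangePreset, active_limbs: str = "all",
                   config: SimConfig | None = None) -> Trajectory:
    """Run a coupled swimming simulation and record the trajectory.

    Water and body start at rest; stroke targets are tracked by stable-PD
    torques; the body and fluid exchange momentum through the coupled
    pressure solve each step.  On numerical blow-up the trajectory recorded
    so far is returned with ``completed = False``.
    """
    config = config or SimConfig()
    grid = config.make_grid()
    solver = PressureSolver(grid)
    state = initial_state(body, preset, active_limbs, config.start_pos)
    n_steps = int(round(config.n_cycles / params.frequency / config.dt))
    dt = config.dt

    kin = KinCache(body, state)
    rec = {"t": [], "com": [], "pos": [], "quat": [], "theta": [], "tau": []}
    heading0 = kin.R_base @ np.array([1.0, 0, 0])
    lateral0 = kin.R_base @ np.array([0.0, 1, 0])
    up0 = kin.R_base @ np.array([0.0, 0, 1])
    snapshots, diags = [], []

    def record(state, kin, tau):
        rec["t"].append(state.t)
        rec["com"].append(_body_com(body, kin))
        rec["pos"].append(state.pos.copy())
        rec["quat"].append(state.quat.copy())
        rec["theta"].append(state.theta.copy())
        rec["tau"].append(tau.copy())

    record(state, kin, np.zeros(12))
    completed = True
    eps = 1e-4
    for step in range(n_steps):
        t_next = state.t + dt
        tgt = np.deg2rad(st.joint_targets(params, t_next, active_limbs, preset))
        tgt_d = np.deg2rad(
            st.joint_targets(params, t_next + eps, active_limbs, preset)
            - st.joint_targets(params, t_next - eps, active_limbs, preset)
        ) / (2 * eps)
        try:
            state, diag = coupled_step(
                body, state, grid, tgt, tgt_d, dt, solver,
                gravity_on=config.gravity_on, subres=config.subres,
            )
        except (FloatingPointError, RuntimeError) as exc:
            warnings.warn(f"simulation aborted at t={state.t:.3f}: {exc}")
            completed = False
            break
        diags.append(diag)
        if (step + 1) % config.record_every == 0:
            kin = KinCache(body, state)
            tau = bd.spd_torques(body, state, tgt, tgt_d, dt)
            record(state, kin, tau)
        if config.snapshot_every and (step + 1) % config.snapshot_every == 0:
            snapshots.append((state.t, grid.copy_velocity()))
    return Trajectory(
        t=np.array(rec["t"]), com=np.array(rec["com"]),
        base_pos=np.array(rec["pos"]), base_quat=np.array(rec["quat"]),
        theta=np.array(rec["theta"]), torque=np.array(rec["tau"]),
        heading0=heading0, up0=up0, lateral0=lateral0,
        frequency=params.frequency, completed=completed,
        snapshots=snapshots, diagnostics=diags,
    )


def _quat_angle(q1: np.ndarray, q2: np.ndarray) -> float:
    """Geodesic angle between two unit quaternions (rad)."""
    d = abs(float(np.dot(q1, q2)))
    return 2.0 * np.arccos(min(1.0, d))


def quality(traj: Trajectory, w_dir: float = 1.0, w_orient: float = 0.5,
            cycle: int = 1) -> QualityResult:
    """Straight-swimming quality over one stroke cycle (default: second).

    The metric window is cycle index ``cycle`` (0-based); the start-up
    cycle 0 is excluded because the swimmer accelerates from rest.  All
    quantities are measured in the initial-heading frame, so the result is
    invariant to the starting position and orientation.
    """
    period = 1.0 / traj.frequency
    t0, t1 = cycle * period, (cycle + 1) * period
    if traj.t[-1] < t1 - 1e-9:
        raise ValueError(
            f"trajectory ends at {traj.t[-1]:.2f}s; need {t1:.2f}s for cycle {cycle}"
        )
    i0 = int(np.argmin(np.abs(traj.t - t0)))
    i1 = int(np.argmin(np.abs(traj.t - t1)))
    d = traj.com[i1] - traj.com[i0]
    fwd = float(np.dot(d, traj.heading0))
    lat = float(np.dot(d, traj.lateral0))
    vert = float(np.dot(d, traj.up0))
    dorient = _quat_angle(traj.base_quat[i0], traj.base_quat[i1])
    qv = fwd - w_dir * float(np.hypot(lat, vert)) - w_orient * abs(dorient)
    return QualityResult(
        forward_distance=fwd, lateral_deviation=lat, vertical_deviation=vert,
        orientation_deviation=dorient,
        mean_speed=fwd / period, quality=qv,
    )


def tip_traces(traj: Trajectory, body: ArticulatedBody) -> dict:
    """World-space paths of the distal flipper tips (dict name -> (n,3))."""
    tips = {}
    for name in bd.FLIPPERS:
        mesh = body.links[name].mesh
        # distal tip: the vertex farthest from the pivot along the span
        vi = int(np.argmax(np.abs(mesh.vertices[:, 1])))
        tips[name] = mesh.vertices[vi]
    out = {name: np.empty((len(traj.t), 3)) for name in bd.FLIPPERS}
    for i in range(len(traj.t)):
        state = BodyState(pos=traj.base_pos[i], quat=traj.base_quat[i],
                          theta=traj.theta[i])
        kin = KinCache(body, state)
        for name in bd.FLIPPERS:
            out[name][i] = kin.pivot_w[name] + kin.link_R[name] @ tips[name]
    return out


def _vorticity_magnitude(grid: MacGrid, u, pts: np.ndarray) -> np.ndarray:
    """|curl u| at points via central differences of sampled velocity."""
    from .fluid_grid import sample_velocity
    saved = grid.u
    grid.u = u
    h = grid.dx
    grad = np.empty((len(pts), 3, 3))
    for a in range(3):
        e = np.zeros(3)
        e[a] = h
        grad[:, :, a] = (sample_velocity(grid, pts + e) - sample_velocity(grid, pts - e)) / (2 * h)
    grid.u = saved
    wx = grad[:, 2, 1] - grad[:, 1, 2]
    wy = grad[:, 0, 2] - grad[:, 2, 0]
    wz = grad[:, 1, 0] - grad[:, 0, 1]
    return np.sqrt(wx**2 + wy**2 + wz**2)


def particle_traces(grid: MacGrid, snapshots: list, n_particles: int = 500,
                    vorticity_threshold: float = 1.5, seed: int = 0,
                    trace_steps: int = 5) -> list:
    """Passively advected particle traces, kept only in high-vorticity flow.

    ``snapshots`` is the ``Trajectory.snapshots`` list of (t, velocity
    fields).  Particles are seeded uniformly in the domain and advected
    through consecutive snapshots; a trace is reported when the vorticity
    magnitude at the particle exceeds ``vorticity_threshold`` (s^-1) at any
    point along it.  Returns a list of (n_steps, 3) arrays.
    """
    if not snapshots:
        return []
    rng = np.random.default_rng(seed)
    dom = np.array(grid.shape) * grid.dx
    pts = grid.origin + rng.uniform(0.05, 0.95, size=(n_particles, 3)) * dom
    paths = [pts.copy()]
    vmax = np.zeros(n_particles)
    use = snapshots[-trace_steps:]
    from .fluid_grid import sample_velocity
    saved = grid.u
    for i in range(len(use)):
        t_i, u_i = use[i]
        grid.u = u_i
        dt = (use[i + 1][0] - t_i) if i + 1 < len(use) else (t_i - use[i - 1][0] if i else 0.01)
        vmax = np.maximum(vmax, _vorticity_magnitude(grid, u_i, pts))
        pts = pts + dt * sample_velocity(grid, pts)
        paths.append(pts.copy())
    grid.u = saved
    mask = vmax > vorticity_threshold
    stack = np.stack(paths, axis=1)  # (n_particles, steps, 3)
    return [stack[i] for i in np.nonzero(mask)[0]]


def reference_stroke(preset_name: str = "medium", limbs: str = "all") -> st.StrokeParams:
    """A published-parameter underwater-flight stroke (see packaged data).

    Built from the achieved joint ranges, time asymmetries and rotation
    holds of the optimized medium-range strokes, with phases following the
    flight-stroke convention (rotation plateau during the downstroke).
    Useful as a realistic input where running a full optimization is not
    warranted.
    """
    raw = json.loads(
        resources.files("plesioswim.data").joinpath("reference_strokes.json").read_text()
    )
    table = raw[preset_name][limbs]
    period = 1.0 / st.STROKE_FREQUENCY_HZ

    def limb_from(d) -> st.LimbStroke:
        specs = {
            dof: st.SinusoidSpec(d[dof]["min"], d[dof]["max"], d[dof]["phase"], d[dof]["asym"])
            for dof in st.DOF_NAMES
        }
        return st.LimbStroke(specs["dv"], specs["ap"], specs["rot"], d["hold"])

    neutral_limb = st.LimbStroke(
        st.SinusoidSpec(0.0, 0.0, 0.0), st.SinusoidSpec(0.0, 0.0, 0.0),
        st.SinusoidSpec(0.0, 0.0, 0.0), 0.0,
    )
    fore = limb_from(table["fore"]) if "fore" in table else neutral_limb
    hind = limb_from(table["hind"]) if "hind" in table else neutral_limb
    return st.StrokeParams(fore=fore, hind=hind)
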