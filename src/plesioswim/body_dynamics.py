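"""Articulated rigid-body dynamics in generalized coordinates.

The swimmer is a floating-base tree: one torso link (6 free DOFs) with four
flipper links, each attached by a 3-DOF ball joint decomposed into a fixed
sequence of rotations (dorsoventral, anteroposterior, long-axis rotation).
Generalized coordinates are ``q = [base position (3), base orientation (3),
joint angles (12)]``; the base orientation block is parameterized
singularity-free by a unit quaternion carried in the state, with the three
rotational velocity coordinates being the world-frame angular velocity.

Equations of motion: ``M(q) q̈ + C(q, q̇) = τ_int + τ_ext`` with the mass
matrix assembled from link Jacobians and the bias vector from their time
derivatives (evaluated by differencing the Jacobians along the state flow)
plus the gyroscopic term.  Joint actuation uses a stable implicit-damping
proportional-derivative law; integration is semi-implicit Euler at the
fluid time step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .geometry import Mesh

__all__ = [
    "RigidLink",
    "Joint",
    "ArticulatedBody",
    "BodyState",
    "N_DOF",
    "LINK_NAMES",
    "quat_to_matrix",
    "quat_exp_step",
    "kinematic_cache",
    "posed_meshes",
    "mass_matrix",
    "bias_forces",
    "gravity_force",
    "spd_torques",
    "integrate",
    "interface_kinematics",
    "surface_point_rows",
]

N_DOF = 18
LINK_NAMES = ("torso", "fore_left", "fore_right", "hind_left", "hind_right")
FLIPPERS = LINK_NAMES[1:]

#: fluid/body density, kg/m^3 (the body is neutrally buoyant)
DENSITY = 1000.0


@dataclass
class RigidLink:
    """One rigid link: mesh in link-local frame plus mass properties."""

    name: str
    mesh: Mesh
    mass: float
    com: np.ndarray          # COM in link-local frame
    inertia: np.ndarray      # 3x3 about COM, link-local frame


@dataclass
class Joint:
    """3-DOF ball joint: pivot and rotation-axis sequence in the base frame."""

    name: str
    pivot: np.ndarray        # pivot position in base (torso COM) frame
    axes: np.ndarray         # (3,3) rows: dv, ap, rot axes at zero pose


@dataclass
class ArticulatedBody:
    """Torso + four flippers with joints; see :func:`plesioswim.geometry.build_swimmer`."""

    spec: object
    links: dict
    joints: dict
    kp: np.ndarray = field(default_factory=lambda: np.full(12, 6000.0))
    kd: np.ndarray = field(default_factory=lambda: np.full(12, 300.0))

    @property
    def total_mass(self) -> float:
        return sum(l.mass for l in self.links.values())

    def joint_of(self, link_name: str) -> Joint:
        return self.joints[link_name]

    def describe(self) -> dict:
        """JSON-serializable model description."""
        out = {"links": {}, "joints": {}}
        for n, l in self.links.items():
            out["links"][n] = {
                "mass": l.mass,
                "com": list(map(float, l.com)),
                "inertia": np.asarray(l.inertia).tolist(),
                "n_vertices": int(len(l.mesh.vertices)),
            }
        for n, j in self.joints.items():
            out["joints"][n] = {
                "pivot": list(map(float, j.pivot)),
                "axes": np.asarray(j.axes).tolist(),
            }
        return out


@dataclass
class BodyState:
    """Generalized state: base pose (quaternion orientation) + joint angles.

    ``theta``/``theta_dot`` are radians ordered fore-left, fore-right,
    hind-left, hind-right, each (dv, ap, rot).  ``omega`` is the world-frame
    angular velocity of the base.
    """

    pos: np.ndarray = field(default_factory=lambda: np.zeros(3))
    quat: np.ndarray = field(default_factory=lambda: np.array([1.0, 0, 0, 0]))
    vel: np.ndarray = field(default_factory=lambda: np.zeros(3))
    omega: np.ndarray = field(default_factory=lambda: np.zeros(3))
    theta: np.ndarray = field(default_factory=lambda: np.zeros(12))
    theta_dot: np.ndarray = field(default_factory=lambda: np.zeros(12))
    t: float = 0.0

    @property
    def qdot(self) -> np.ndarray:
        return np.concatenate([self.vel, self.omega, self.theta_dot])

    def copy(self) -> "BodyState":
        return BodyState(self.pos.copy(), self.quat.copy(), self.vel.copy(),
                         self.omega.copy(), self.theta.copy(),
                         self.theta_dot.copy(), self.t)


# ---------------------------------------------------------------------------
# quaternion helpers (w, x, y, z)

def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q / np.linalg.norm(q)
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def quat_exp_step(q: np.ndarray, omega_world: np.ndarray, dt: float) -> np.ndarray:
    """Rotate ``q`` by the world-frame angular velocity over ``dt``."""
    th = np.linalg.norm(omega_world) * dt
    if th < 1e-14:
        return q / np.linalg.norm(q)
    axis = omega_world / np.linalg.norm(omega_world)
    dq = np.concatenate([[np.cos(th / 2)], np.sin(th / 2) * axis])
    w1, x1, y1, z1 = dq
    w2, x2, y2, z2 = q
    out = np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ])
    return out / np.linalg.norm(out)


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    a = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def _skew(v):
    return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0.0]])


# ---------------------------------------------------------------------------
# kinematics

class KinCache:
    """Per-state forward-kinematics quantities shared by all operations."""

    __slots__ = ("R_base", "pos", "link_R", "link_com", "pivot_w", "axes_w",
                 "joint_slice", "Jv", "Jw")

    def __init__(self, body: ArticulatedBody, state: BodyState):
        self.R_base = quat_to_matrix(state.quat)
        self.pos = state.pos.copy()
        self.link_R = {}
        self.link_com = {}
        self.pivot_w = {}
        self.axes_w = {}
        self.joint_slice = {}
        torso = body.links["torso"]
        self.link_R["torso"] = self.R_base
        self.link_com["torso"] = state.pos + self.R_base @ torso.com
        for jidx, name in enumerate(FLIPPERS):
            if name not in body.links:
                continue
            joint = body.joints[name]
            th = state.theta[3 * jidx: 3 * jidx + 3]
            R1 = _axis_angle(joint.axes[0], th[0])
            R2 = _axis_angle(joint.axes[1], th[1])
            R3 = _axis_angle(joint.axes[2], th[2])
            Rj = R1 @ R2 @ R3
            a1 = self.R_base @ joint.axes[0]
            a2 = self.R_base @ (R1 @ joint.axes[1])
            a3 = self.R_base @ (R1 @ R2 @ joint.axes[2])
            self.axes_w[name] = np.stack([a1, a2, a3])
            self.pivot_w[name] = state.pos + self.R_base @ joint.pivot
            RL = self.R_base @ Rj
            self.link_R[name] = RL
            self.link_com[name] = self.pivot_w[name] + RL @ body.links[name].com
            self.joint_slice[name] = slice(6 + 3 * jidx, 9 + 3 * jidx)
        # COM jacobians per link
        self.Jv = {}
        self.Jw = {}
        for name in LINK_NAMES:
            if name not in body.links:
                continue
            Jv = np.zeros((3, N_DOF))
            Jw = np.zeros((3, N_DOF))
            Jv[:, 0:3] = np.eye(3)
            Jw[:, 3:6] = np.eye(3)
            p = self.link_com[name]
            Jv[:, 3:6] = -_skew(p - state.pos)
            if name != "torso":
                sl = self.joint_slice[name]
                piv = self.pivot_w[name]
                for i in range(3):
                    a = self.axes_w[name][i]
                    Jw[:, sl.start + i] = a
                    Jv[:, sl.start + i] = np.cross(a, p - piv)
            self.Jv[name] = Jv
            self.Jw[name] = Jw


def kinematic_cache(body: ArticulatedBody, state: BodyState) -> KinCache:
    return KinCache(body, state)


def posed_meshes(body: ArticulatedBody, state: BodyState, kin: KinCache | None = None):
    """World-frame link meshes for the current pose (dict name -> Mesh)."""
    kin = kin or KinCache(body, state)
    out = {}
    for name in LINK_NAMES:
        if name not in body.links:
            continue
        link = body.links[name]
        if name == "torso":
            out[name] = link.mesh.transformed(kin.R_base, state.pos)
        else:
            out[name] = link.mesh.transformed(kin.link_R[name], kin.pivot_w[name])
    return out


def _advanced_state(state: BodyState, eps: float) -> BodyState:
    s = state.copy()
    s.pos = state.pos + eps * state.vel
    s.quat = quat_exp_step(state.quat, state.omega, eps)
    s.theta = state.theta + eps * state.theta_dot
    s.t = state.t + eps
    return s


# ---------------------------------------------------------------------------
# dynamics terms

def mass_matrix(body: ArticulatedBody, state: BodyState, kin: KinCache | None = None) -> np.ndarray:
    """Symmetric positive-definite 18x18 generalized mass matrix."""
    kin = kin or KinCache(body, state)
    M = np.zeros((N_DOF, N_DOF))
    for name in body.links:
        link = body.links[name]
        Jv, Jw = kin.Jv[name], kin.Jw[name]
        RL = kin.link_R[name]
        Iw = RL @ link.inertia @ RL.T
        M += link.mass * Jv.T @ Jv + Jw.T @ Iw @ Jw
    # absent joints (reduced bodies): unit diagonal, their DOFs carry no
    # forces and remain identically zero
    for jidx, name in enumerate(FLIPPERS):
        if name not in body.links:
            sl = slice(6 + 3 * jidx, 9 + 3 * jidx)
            M[sl, sl] = np.eye(3)
    return 0.5 * (M + M.T)


def bias_forces(body: ArticulatedBody, state: BodyState, kin: KinCache | None = None,
                eps: float = 1e-6) -> np.ndarray:
    """Coriolis/centrifugal bias vector C(q, q̇) (18,).

    Uses ``C = Σ_L [m J_vᵀ (J̇_v q̇) + J_ωᵀ (I_w (J̇_ω q̇) + ω × I_w ω)]``
    with the Jacobian time derivatives evaluated by central differencing of
    the link Jacobians along the current state flow.
    """
    kin = kin or KinCache(body, state)
    qd = state.qdot
    if not np.any(qd):
        return np.zeros(N_DOF)
    kp = KinCache(body, _advanced_state(state, eps))
    km = KinCache(body, _advanced_state(state, -eps))
    C = np.zeros(N_DOF)
    for name in body.links:
        link = body.links[name]
        dJv = (kp.Jv[name] - km.Jv[name]) / (2 * eps)
        dJw = (kp.Jw[name] - km.Jw[name]) / (2 * eps)
        RL = kin.link_R[name]
        Iw = RL @ link.inertia @ RL.T
        w = kin.Jw[name] @ qd
        C += link.mass * kin.Jv[name].T @ (dJv @ qd)
        C += kin.Jw[name].T @ (Iw @ (dJw @ qd) + np.cross(w, Iw @ w))
    return C


def gravity_force(body: ArticulatedBody, state: BodyState, kin: KinCache | None = None,
                  g=(0.0, 0.0, -9.81)) -> np.ndarray:
    """Generalized gravity force (18,)."""
    kin = kin or KinCache(body, state)
    g = np.asarray(g, float)
    tau = np.zeros(N_DOF)
    for name in body.links:
        tau += body.links[name].mass * (kin.Jv[name].T @ g)
    return tau


def spd_torques(body: ArticulatedBody, state: BodyState, target_theta: np.ndarray,
                target_theta_dot: np.ndarray, dt: float) -> np.ndarray:
    """Stable (implicit-damping) PD joint torques, explicit part (12,).

    ``τ = -k_p (θ + Δt θ̇ - θ̄) - k_d (θ̇ - θ̄̇)``: the proportional term is
    evaluated at the predicted next-step angle.  The remaining implicit
    damping contribution ``-k_d Δt θ̈`` is folded into the acceleration
    solve (see :func:`effective_mass_matrix`); together they keep large
    gains stable at time steps where the explicit law diverges.  Base DOFs
    are never actuated.
    """
    err = state.theta + dt * state.theta_dot - np.asarray(target_theta, float)
    derr = state.theta_dot - np.asarray(target_theta_dot, float)
    return -body.kp * err - body.kd * derr


def effective_mass_matrix(body: ArticulatedBody, M: np.ndarray, dt: float) -> np.ndarray:
    """``M + Δt K_d`` with the joint damping gains on the diagonal.

    Solving ``(M + Δt K_d) q̈ = τ - C`` applies the implicit part of the
    stable-PD law; the same operator is the body's pressure response in the
    two-way coupling (it stays symmetric positive definite).
    """
    Me = M.copy()
    Me[np.arange(6, N_DOF), np.arange(6, N_DOF)] += dt * body.kd
    return Me


def integrate(body: ArticulatedBody, state: BodyState, tau_int: np.ndarray,
              tau_ext: np.ndarray, dt: float, kin: KinCache | None = None,
              M: np.ndarray | None = None, C: np.ndarray | None = None,
              implicit_damping: bool = True) -> BodyState:
    """One semi-implicit Euler step of ``M q̈ + C = τ_int + τ_ext``.

    ``tau_int`` are the 12 joint torques; ``tau_ext`` the full 18-vector of
    external generalized forces (fluid pressure, gravity).  Velocities are
    updated first, positions with the new velocities; the base orientation
    advances along the quaternion exponential.  With ``implicit_damping``
    the stable-PD damping term ``-Δt K_d q̈`` is included in the solve.
    """
    kin = kin or KinCache(body, state)
    M = mass_matrix(body, state, kin) if M is None else M
    C = bias_forces(body, state, kin) if C is None else C
    tau = np.asarray(tau_ext, float).copy()
    tau[6:] += tau_int
    Me = effective_mass_matrix(body, M, dt) if implicit_damping else M
    qdd = np.linalg.solve(Me, tau - C)
    if not np.all(np.isfinite(qdd)):
        raise FloatingPointError("non-finite generalized accelerations; simulation diverged")
    s = state.copy()
    s.vel = state.vel + dt * qdd[0:3]
    s.omega = state.omega + dt * qdd[3:6]
    s.theta_dot = state.theta_dot + dt * qdd[6:]
    s.pos = state.pos + dt * s.vel
    s.quat = quat_exp_step(state.quat, s.omega, dt)
    s.theta = state.theta + dt * s.theta_dot
    s.t = state.t + dt
    return s


# ---------------------------------------------------------------------------
# fluid-surface interface kinematics

_LINK_INDEX = {n: i for i, n in enumerate(LINK_NAMES)}


def surface_point_rows(body: ArticulatedBody, state: BodyState, points: np.ndarray,
                       link_ids: np.ndarray, kin: KinCache | None = None):
    """Vectorized point Jacobians for coupling.

    ``points`` (n,3) world positions attached to links ``link_ids`` (n,)
    indices into :data:`LINK_NAMES`.  Returns ``J`` with shape (n, 3, 18)
    such that the world velocity of point i is ``J[i] @ qdot``.
    """
    kin = kin or KinCache(body, state)
    pts = np.asarray(points, float)
    n = len(pts)
    J = np.zeros((n, 3, N_DOF))
    J[:, 0, 0] = J[:, 1, 1] = J[:, 2, 2] = 1.0
    r = pts - state.pos
    # base rotation block: -skew(r)
    J[:, 0, 4] = r[:, 2]; J[:, 0, 5] = -r[:, 1]
    J[:, 1, 3] = -r[:, 2]; J[:, 1, 5] = r[:, 0]
    J[:, 2, 3] = r[:, 1]; J[:, 2, 4] = -r[:, 0]
    for name in FLIPPERS:
        if name not in body.links:
            continue
        mask = link_ids == _LINK_INDEX[name]
        if not np.any(mask):
            continue
        sl = kin.joint_slice[name]
        rel = pts[mask] - kin.pivot_w[name]
        for i in range(3):
            a = kin.axes_w[name][i]
            J[mask, :, sl.start + i] = np.cross(a[None, :], rel)
    return J


def point_velocities(body: ArticulatedBody, state: BodyState, points, link_ids,
                     kin: KinCache | None = None) -> np.ndarray:
    J = surface_point_rows(body, state, points, link_ids, kin)
    return J @ state.qdot


def _local_coords(body, state, kin, points, link_ids):
    pts = np.asarray(points, float)
    loc = np.empty_like(pts)
    for name in LINK_NAMES:
        if name not in body.links:
            continue
        mask = link_ids == _LINK_INDEX[name]
        if not np.any(mask):
            continue
        if name == "torso":
            loc[mask] = (pts[mask] - state.pos) @ kin.R_base
        else:
            loc[mask] = (pts[mask] - kin.pivot_w[name]) @ kin.link_R[name]
    return loc


def _world_coords(body, state, kin, locs, link_ids):
    out = np.empty_like(locs)
    for name in LINK_NAMES:
        if name not in body.links:
            continue
        mask = link_ids == _LINK_INDEX[name]
        if not np.any(mask):
            continue
        if name == "torso":
            out[mask] = locs[mask] @ kin.R_base.T + state.pos
        else:
            out[mask] = locs[mask] @ kin.link_R[name].T + kin.pivot_w[name]
    return out


def jdot_qdot_rows(body: ArticulatedBody, state: BodyState, points, link_ids,
                   kin: KinCache | None = None, eps: float = 1e-6) -> np.ndarray:
    """Convective acceleration term ``J̇ q̇`` at surface points, (n,3).

    Evaluated by differencing the material-point velocities along the state
    flow at frozen ``q̇`` (central difference, step ``eps`` seconds).
    """
    kin = kin or KinCache(body, state)
    locs = _local_coords(body, state, kin, points, link_ids)
    sp = _advanced_state(state, eps)
    sm = _advanced_state(state, -eps)
    kp_, km_ = KinCache(body, sp), KinCache(body, sm)
    pp = _world_coords(body, sp, kp_, locs, link_ids)
    pm = _world_coords(body, sm, km_, locs, link_ids)
    vp = point_velocities(body, sp, pp, link_ids, kp_)
    vm = point_velocities(body, sm, pm, link_ids, km_)
    return (vp - vm) / (2 * eps)


def interface_kinematics(body: ArticulatedBody, state: BodyState, point, link_name: str,
                         kin: KinCache | None = None):
    """(J 3x18, J̇q̇ 3-vector, surface velocity 3-vector) at one surface point."""
    if link_name not in _LINK_INDEX:
        raise KeyError(f"point not attributable to a link: {link_name!r}")
    ids = np.array([_LINK_INDEX[link_name]])
    pts = np.asarray(point, float)[None, :]
    kin = kin or KinCache(body, state)
    J = surface_point_rows(body, state, pts, ids, kin)[0]
    jdqd = jdot_qdot_rows(body, state, pts, ids, kin)[0]
    return J, jdqd, J @ state.qdot


def mass_cholesky(M: np.ndarray):
    """Cholesky factorization handle for repeated ``M⁻¹`` applications."""
    return cho_factor(0.5 * (M + M.T))


def mass_solve(factor, rhs: np.ndarray) -> np.ndarray:
    return cho_solve(factor, rhs)
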