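"""Quasi-steady drag-paddle surrogate swimmer.

A deliberately cheap stand-in for the full coupled simulation, used to
exercise the optimization machinery end-to-end in seconds: each flipper is
a flat blade whose quasi-steady normal drag produces thrust, the torso
contributes quadratic form drag, and only the forward (surge) degree of
freedom is integrated.  The surrogate shares the stroke model and quality
conventions with the full simulator (cycle-2 forward distance), but none
of its grid hydrodynamics — wake, added mass and body-limb interaction are
absent, so its optima are *not* the full model's optima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import stroke as st

__all__ = ["DragPaddleSwimmer"]


@dataclass
class DragPaddleSwimmer:
    """1-DOF forward-dynamics swimmer with blade-element drag flippers."""

    body_mass: float = 450.0          # kg, torso + limbs
    body_drag_area: float = 0.55      # C_d * frontal area, m^2
    blade_area: float = 0.28          # one flipper planform area, m^2
    blade_arm: float = 0.55           # pivot-to-blade-center distance, m
    blade_cd: float = 2.0             # normal-plate drag coefficient
    rho: float = 1000.0
    dt: float = 0.005
    n_cycles: float = 2.0

    def simulate(self, params: st.StrokeParams, active_limbs: str = "all",
                 preset: st.JointRangePreset | None = None):
        """Integrate surge velocity over the stroke; returns (t, x, U)."""
        preset = preset or st.load_presets()["medium"]
        period = params.period
        n = int(round(self.n_cycles * period / self.dt))
        t = np.arange(n + 1) * self.dt
        ang = np.deg2rad(st.joint_targets(params, t, active_limbs, preset))
        dang = np.gradient(ang, self.dt, axis=0)
        U = np.zeros(n + 1)
        x = np.zeros(n + 1)
        half_rho_a = 0.5 * self.rho * self.blade_area * self.blade_cd
        for i in range(n):
            thrust = 0.0
            for j, (pair, _side) in enumerate(st.JOINT_ORDER):
                dv, ap, rot = ang[i, 3 * j: 3 * j + 3]
                dv_dot = dang[i, 3 * j]
                ap_dot = dang[i, 3 * j + 1]
                # blade normal in the vertical plane, tilted by the pitch
                # (rotation) angle; heave speed of the blade center
                heave = self.blade_arm * dv_dot * np.cos(dv)
                sway = self.blade_arm * ap_dot
                # normal component of the relative flow over the blade:
                # pitch rotates the blade normal from vertical toward x
                nx, nz = np.sin(rot), np.cos(rot)
                v_n = nz * heave + nx * (sway - U[i])
                f = -half_rho_a * abs(v_n) * v_n
                thrust += f * nx
            drag = -0.5 * self.rho * self.body_drag_area * abs(U[i]) * U[i]
            U[i + 1] = U[i] + self.dt * (thrust + drag) / self.body_mass
            x[i + 1] = x[i] + self.dt * U[i + 1]
        return t, x, U

    def quality(self, params: st.StrokeParams, active_limbs: str = "all",
                preset: st.JointRangePreset | None = None) -> float:
        """Cycle-2 forward distance (m); the surrogate swims exactly straight."""
        t, x, _ = self.simulate(params, active_limbs, preset)
        period = params.period
        i0 = int(np.argmin(np.abs(t - period)))
        i1 = int(np.argmin(np.abs(t - 2 * period)))
        return float(x[i1] - x[i0])
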