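"""Pure-fluid solver demo: hydrostatics and BFECC advection.

A still column of water under gravity is pressure-projected once: the
pressure profile reproduces rho*g*depth and the velocities return to zero.
Then a Gaussian blob is advected 20 steps with BFECC vs plain
semi-Lagrangian to show the reduced numerical diffusion.
"""

import numpy as np

from plesioswim import fluid_grid as fg

g = fg.MacGrid(shape=(16, 16, 32), dx=0.1)
fg.apply_gravity(g, 0.01)
p = fg.project_pure_fluid(g, 0.01)
zc = (np.arange(32) + 0.5) * 0.1
expect = 1000 * 9.81 * (3.2 - zc)
err = np.abs(p[8, 8, :] - expect).max() / expect.max()
print(f"hydrostatic pressure error: {100 * err:.2e} %  "
      f"(p at mid-depth {p[8, 8, 16]:.0f} Pa, analytic {expect[16]:.0f} Pa)")
print(f"residual speed after projection: {g.max_speed():.2e} m/s")

g = fg.MacGrid(shape=(48, 24, 24), dx=1.0)
g.g[:] = 0.0
g.u[0][:] = 1.0
X = g.cell_centers()
blob = np.exp(-0.5 * np.sum((X - [10, 12, 12]) ** 2, axis=-1) / 4.0)
fb, fs = blob, blob
for _ in range(20):
    fb = fg.advect_scalar_bfecc(g, fb, 0.6)
    fs = fg.advect_scalar_semi_lagrangian(g, fs, 0.6)
print(f"\nblob peak after 20 advection steps: BFECC {fb.max():.3f}, "
      f"semi-Lagrangian {fs.max():.3f} (initial 1.0)")
# BFECC's error compensation keeps substantially more of the peak, i.e.
# less numerical viscosity around the swimmer.
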