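"""Full coupled swimming simulation at the desk-scale grid.

Runs the reference forelimb-only underwater-flight stroke for two cycles
(4 s) on the 50x40x30 grid and prints the cycle-2 straight-swimming
quality.  Takes a minute or two on one CPU.
"""

from plesioswim.geometry import build_swimmer
from plesioswim.stroke import load_presets
from plesioswim.swim import SimConfig, quality, reference_stroke, run_simulation

body = build_swimmer()
preset = load_presets()["medium"]
params = reference_stroke("medium", "fore")
cfg = SimConfig(grid="desk", n_cycles=2.0)

traj = run_simulation(body, params, preset, "fore", cfg)
q = quality(traj, cfg.w_dir, cfg.w_orient)
print(f"cycle-2 forward distance : {q.forward_distance:.3f} m")
print(f"mean speed               : {q.mean_speed:.3f} m/s")
print(f"lateral deviation        : {q.lateral_deviation * 1e3:.2f} mm")
print(f"vertical deviation       : {q.vertical_deviation:.3f} m")
print(f"orientation change       : {q.orientation_deviation:.3f} rad")
print(f"quality q(s)             : {q.quality:.3f}")
# The stroke is bilaterally symmetric, so the lateral deviation is a tiny
# fraction of the forward travel; absolute distances at this coarse grid
# are smaller than at the full-scale resolution.
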