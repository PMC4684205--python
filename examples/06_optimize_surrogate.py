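"""CMA-ES stroke search on the quasi-steady drag-paddle surrogate.

The surrogate replaces the grid fluid with blade-element drag, so a full
13-parameter forelimb-stroke optimization runs in seconds.  The same
`run_experiment` call drives the full coupled simulator when no evaluator
is passed (budget: hours, cluster-friendly via `n_workers`).
"""

from plesioswim.optimize import OptConfig, run_experiment
from plesioswim.surrogate import DragPaddleSwimmer

paddle = DragPaddleSwimmer()
cfg = OptConfig(population=8, max_iter=25, seed=1)
run, result = run_experiment(
    "medium", "fore", "slim", cfg,
    evaluator=lambda p, limbs, preset: paddle.quality(p, limbs, preset))

print(f"search dimension          : {len(run.best_x)} (9 sinusoid values "
      f"+ 3 asymmetries + 1 hold)")
print(f"evaluations               : {run.n_evaluations}")
print(f"best surrogate distance   : {run.best_quality:.3f} m per cycle")
best = result["params"].fore
print(f"best dorsoventral range   : [{best.dorsoventral.min_angle:.1f}, "
      f"{best.dorsoventral.max_angle:.1f}] deg")
print(f"best rotation hold        : {best.rotation_hold:.2f} s")
# Surrogate optima are not the full model's optima (no wake, no added
# mass), but the optimizer plumbing, bounds and encodings are identical.
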