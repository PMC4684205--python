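"""CMA-ES stroke search and the experiment grid.

Covariance matrix adaptation evolution strategy (CMA-ES) searches the
26-dimensional stroke space (13-dimensional for single-pair experiments)
for the stroke maximizing the straight-swimming quality.  The
implementation follows the standard (mu/mu_w, lambda) formulation: each
iteration draws ``population`` samples from a multivariate Gaussian, ranks
them by quality, and updates the distribution mean, two evolution paths,
the covariance (rank-1 + rank-mu) and the step size.  Box bounds are
handled by resampling, falling back to clipping with a quadratic penalty.

The experiment grid mirrors the study design: three joint-range presets
(narrow / medium / wide) crossed with three active-limb sets (all / fore /
hind), plus a slim-vs-bulky body comparison that re-simulates fixed
strokes on the bulkier body without re-optimizing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stroke as st
from .geometry import BodySpec, build_swimmer
from .swim import SimConfig, quality, run_simulation

__all__ = ["OptConfig", "OptRun", "CMAES", "cma_optimize", "run_experiment",
           "compare_body_variants"]


@dataclass
class OptConfig:
    """CMA-ES settings (defaults follow the study: 31 samples, ~70 iters)."""

    population: int = 31
    max_iter: int = 70
    seed: int = 0
    sigma0_frac: float = 0.3     # initial sigma = frac * box width
    n_workers: int = 1
    resample_limit: int = 50
    penalty: float = 1e3         # quality penalty per squared unit outside box
    tol_stagnation: int = 0      # 0 = run all iterations

    def __post_init__(self):
        if self.population < 4:
            raise ValueError("population must be >= 4")


@dataclass
class OptRun:
    """Archive of one optimization run."""

    best_x: np.ndarray
    best_quality: float
    iterations: list               # per-iteration dicts (best, mean, sigma)
    n_evaluations: int
    seed: int
    archive: list = field(default_factory=list)

    @property
    def best_per_iteration(self) -> np.ndarray:
        return np.array([it["best_so_far"] for it in self.iterations])


class CMAES:
    """Minimal deterministic CMA-ES with box bounds (maximizes ``objective``)."""

    def __init__(self, x0, sigma0, lower, upper, population, seed,
                 resample_limit=50, penalty=1e3):
        self.n = len(x0)
        self.mean = np.asarray(x0, float).copy()
        self.sigma = float(sigma0)
        self.lower = np.asarray(lower, float)
        self.upper = np.asarray(upper, float)
        self.lam = int(population)
        self.rng = np.random.default_rng(seed)
        self.resample_limit = resample_limit
        self.penalty = penalty
        # standard strategy parameters with active (negative-weight)
        # recombination, following Hansen's tutorial defaults
        n, lam = self.n, self.lam
        self.mu = lam // 2
        w_raw = np.log((lam + 1) / 2) - np.log(np.arange(1, lam + 1))
        w_pos = w_raw[: self.mu]
        self.mueff = w_pos.sum() ** 2 / np.sum(w_pos**2)
        mueff_neg = (w_raw[self.mu:].sum() ** 2 / np.sum(w_raw[self.mu:] ** 2)
                     if lam > self.mu else 1.0)
        self.cc = (4 + self.mueff / n) / (n + 4 + 2 * self.mueff / n)
        self.cs = (self.mueff + 2) / (n + self.mueff + 5)
        self.c1 = 2.0 / ((n + 1.3) ** 2 + self.mueff)
        self.cmu = min(1 - self.c1,
                       2 * (self.mueff - 2 + 1 / self.mueff) / ((n + 2) ** 2 + self.mueff))
        # full-length weights: positives sum to 1, negatives scaled so the
        # covariance stays positive definite
        w = w_raw.copy()
        w[: self.mu] = w_pos / w_pos.sum()
        if lam > self.mu:
            a_mu = 1 + self.c1 / max(self.cmu, 1e-12)
            a_mueff = 1 + 2 * mueff_neg / (self.mueff + 2)
            a_pos = (1 - self.c1 - self.cmu) / (n * max(self.cmu, 1e-12))
            neg = w_raw[self.mu:]
            w[self.mu:] = -min(a_mu, a_mueff, a_pos) * neg / np.abs(neg).sum()
        self.weights_full = w
        self.weights = w[: self.mu]
        self.damps = 1 + 2 * max(0.0, np.sqrt((self.mueff - 1) / (n + 1)) - 1) + self.cs
        self.pc = np.zeros(n)
        self.ps = np.zeros(n)
        self.C = np.eye(n)
        self.gen = 0
        self.chiN = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))
        self._decompose()

    def _decompose(self):
        self.C = 0.5 * (self.C + self.C.T)
        vals, vecs = np.linalg.eigh(self.C)
        vals = np.maximum(vals, 1e-20)
        self.B = vecs
        self.D = np.sqrt(vals)
        self.invsqrtC = vecs @ np.diag(1.0 / self.D) @ vecs.T

    def ask(self):
        """Draw ``lam`` samples, resampling out-of-box draws; returns
        (points, raw z-steps, penalties)."""
        X = np.empty((self.lam, self.n))
        Z = np.empty((self.lam, self.n))
        pen = np.zeros(self.lam)
        for k in range(self.lam):
            for _try in range(self.resample_limit):
                z = self.rng.standard_normal(self.n)
                x = self.mean + self.sigma * (self.B @ (self.D * z))
                if np.all(x >= self.lower) and np.all(x <= self.upper):
                    break
            xc = np.clip(x, self.lower, self.upper)
            pen[k] = self.penalty * float(np.sum((x - xc) ** 2))
            X[k] = xc
            Z[k] = z
        return X, Z, pen

    def tell(self, Z, fitness):
        """Rank by fitness (higher better) and update the distribution."""
        order = np.argsort(-np.asarray(fitness))
        zsort = Z[order]
        zmean = self.weights @ zsort[: self.mu]
        ymean = self.B @ (self.D * zmean)
        self.mean = self.mean + self.sigma * ymean
        self.ps = (1 - self.cs) * self.ps + np.sqrt(
            self.cs * (2 - self.cs) * self.mueff) * (self.B @ zmean)
        self.gen += 1
        hsig = (np.linalg.norm(self.ps)
                / np.sqrt(1 - (1 - self.cs) ** (2 * self.gen))) / self.chiN < 1.4 + 2 / (self.n + 1)
        self.pc = (1 - self.cc) * self.pc + hsig * np.sqrt(
            self.cc * (2 - self.cc) * self.mueff) * ymean
        ys = (self.D * zsort) @ self.B.T          # y_k = B D z_k, ranked
        w = self.weights_full.copy()
        neg = w < 0
        if np.any(neg):
            # scale negative weights by n / ||C^{-1/2} y||^2 = n / ||z||^2
            nz = np.sum(zsort[neg] ** 2, axis=1)
            w[neg] *= self.n / np.maximum(nz, 1e-12)
        rank_mu = ys.T @ (w[:, None] * ys)
        self.C = ((1 - self.c1 - self.cmu * self.weights_full.sum()) * self.C
                  + self.c1 * (np.outer(self.pc, self.pc)
                               + (not hsig) * self.cc * (2 - self.cc) * self.C)
                  + self.cmu * rank_mu)
        self.sigma *= np.exp((self.cs / self.damps)
                             * (np.linalg.norm(self.ps) / self.chiN - 1))
        self._decompose()


def _evaluate_all(objective, X, n_workers):
    if n_workers <= 1:
        return [objective(x) for x in X]
    from joblib import Parallel, delayed
    return Parallel(n_jobs=n_workers)(delayed(objective)(x) for x in X)


def cma_optimize(objective, lower, upper, config: OptConfig,
                 x0=None, keep_archive: bool = False) -> OptRun:
    """Maximize ``objective`` over the box [lower, upper] with CMA-ES.

    ``objective`` maps a parameter vector to a scalar quality; non-finite
    returns are treated as worst-in-iteration.  Fixed ``config.seed`` gives
    a bit-identical sample sequence; parallel evaluation (``n_workers``)
    changes only wall time, not results.

    The search runs in box-normalized coordinates (each coordinate mapped
    to [0, 1]), so the initial step is ``sigma0_frac`` of each coordinate's
    own box width regardless of units.
    """
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)
    width = upper - lower
    if np.any(width <= 0):
        raise ValueError("upper must exceed lower in every coordinate")
    if x0 is None:
        x0 = 0.5 * (lower + upper)
    u0 = (np.asarray(x0, float) - lower) / width

    raw_objective = objective

    def objective(u):
        return raw_objective(lower + u * width)

    es = CMAES(u0, config.sigma0_frac, np.zeros(len(u0)), np.ones(len(u0)),
               config.population, config.seed,
               config.resample_limit, config.penalty)
    best_x, best_q = None, -np.inf
    iterations, archive = [], []
    n_eval = 0
    for it in range(config.max_iter):
        X, Z, pen = es.ask()
        fit = np.asarray(_evaluate_all(objective, X, config.n_workers), float)
        n_eval += len(X)
        bad = ~np.isfinite(fit)
        if np.all(bad):
            raise RuntimeError("all samples failed evaluation; aborting with archive")
        fit[bad] = np.min(fit[~bad]) - 1.0
        fit_pen = fit - pen
        k = int(np.argmax(fit_pen))
        if fit_pen[k] > best_q:
            best_q = float(fit_pen[k])
            best_x = lower + X[k] * width
        es.tell(Z, fit_pen)
        iterations.append({
            "iter": it, "best": float(np.max(fit_pen)),
            "mean": float(np.mean(fit_pen)), "sigma": float(es.sigma),
            "best_so_far": best_q,
        })
        if keep_archive:
            archive.append((X.copy(), fit.copy()))
    return OptRun(best_x=best_x, best_quality=best_q, iterations=iterations,
                  n_evaluations=n_eval, seed=config.seed, archive=archive)


# ---------------------------------------------------------------------------
# experiment grid

def _stroke_objective(preset, active_limbs, body, sim_config, mask, template):
    """Objective over the free (masked) coordinates of the 26-vector."""

    def objective(x_free):
        v = template.copy()
        v[mask] = x_free
        params = st.decode(v, preset, warn_on_swap=False)
        traj = run_simulation(body, params, preset, active_limbs, sim_config)
        if not traj.completed:
            return -np.inf
        q = quality(traj, w_dir=sim_config.w_dir, w_orient=sim_config.w_orient)
        return q.quality

    return objective


def _initial_mean(lower, upper, mask):
    """Mid-range angles, 0.25 phases, symmetric timing, zero hold."""
    x = 0.5 * (lower + upper)
    for ip in range(2):
        for k in range(3):
            x[9 * ip + 3 * k + 2] = 0.25     # phase
        x[18 + 3 * ip: 21 + 3 * ip] = 0.5    # asymmetry
        x[24 + ip] = 0.0                     # hold
    return x[mask]


def run_experiment(preset_name: str, limbs: str, body_variant: str = "slim",
                   opt_config: OptConfig | None = None,
                   sim_config: SimConfig | None = None,
                   evaluator=None, presets=None):
    """Optimize one cell of the experiment grid; returns (OptRun, best info).

    ``limbs`` in {all, fore, hind}: single-pair experiments search the
    reduced 13-D space (9 sinusoid values + 3 asymmetries + 1 hold).
    ``evaluator`` may replace the full simulation objective (e.g. the
    drag-paddle surrogate) with signature ``evaluator(StrokeParams, limbs,
    preset) -> quality``.  After the search the best sample is re-simulated
    and archived.
    """
    presets = presets or st.load_presets()
    preset = presets[preset_name]
    opt_config = opt_config or OptConfig()
    sim_config = sim_config or SimConfig()
    lower, upper, mask = st.parameter_bounds(preset, limbs)
    template = np.concatenate([
        st.encode(st.StrokeParams(
            fore=_neutral_limb(preset, "fore"), hind=_neutral_limb(preset, "hind")))
    ])
    spec = BodySpec(muscle_bulk_factor=1.5 if body_variant == "bulky" else 1.0)
    body = build_swimmer(spec)
    if evaluator is None:
        objective = _stroke_objective(preset, limbs, body, sim_config, mask, template)
    else:
        def objective(x_free):
            v = template.copy()
            v[mask] = x_free
            return evaluator(st.decode(v, preset, warn_on_swap=False), limbs, preset)
    x0 = _initial_mean(lower, upper, mask)
    run = cma_optimize(objective, lower[mask], upper[mask], opt_config, x0=x0)
    v = template.copy()
    v[mask] = run.best_x
    best_params = st.decode(v, preset, warn_on_swap=False)
    result = {"params": best_params, "vector": v, "preset": preset_name,
              "limbs": limbs, "body_variant": body_variant}
    if evaluator is None:
        traj = run_simulation(body, best_params, preset, limbs, sim_config)
        result["trajectory"] = traj
        result["quality"] = quality(traj, sim_config.w_dir, sim_config.w_orient)
    return run, result


def _neutral_limb(preset, pair):
    dv, ap, rot = st.neutral_pose(preset, pair)
    return st.LimbStroke(
        st.SinusoidSpec(dv, dv, 0.0), st.SinusoidSpec(ap, ap, 0.0),
        st.SinusoidSpec(rot, rot, 0.0), 0.0,
    )


def compare_body_variants(stroke_sets: dict, preset_name: str = "medium",
                          sim_config: SimConfig | None = None,
                          presets=None) -> pd.DataFrame:
    """Re-simulate fixed strokes on the slim and bulky bodies.

    ``stroke_sets`` maps an active-limb label to a
    :class:`plesioswim.stroke.StrokeParams` (typically strokes optimized on
    the slim body; the bulky body is *not* re-optimized).  Returns a table
    of forward distance and vertical deviation per (limbs, variant).
    """
    presets = presets or st.load_presets()
    preset = presets[preset_name]
    sim_config = sim_config or SimConfig()
    rows = []
    for variant, bulk in (("slim", 1.0), ("bulky", 1.5)):
        body = build_swimmer(BodySpec(muscle_bulk_factor=bulk))
        for limbs, params in stroke_sets.items():
            traj = run_simulation(body, params, preset, limbs, sim_config)
            q = quality(traj, sim_config.w_dir, sim_config.w_orient)
            rows.append({
                "limbs": limbs, "variant": variant,
                "distance_m": q.forward_distance,
                "vertical_deviation_m": abs(q.vertical_deviation),
                "speed_m_s": q.mean_speed,
                "completed": traj.completed,
            })
    return pd.DataFrame(rows)
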