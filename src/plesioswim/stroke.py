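"""Periodic stroke model for a four-flippered underwater swimmer.

Each of the four limbs articulates at a single 3-DOF ball joint, decomposed
into a dorsoventral (dv) flap, an anteroposterior (ap) sweep, and a
pronation/supination rotation (rot) about the limb's long axis.  Every DOF
follows a modified sinusoid described by a minimum angle, a maximum angle and
a phase.  Two modifications extend the pure sinusoid:

* a *time asymmetry* ``a`` in (0, 1): the half-cycle sweeping toward the
  power-stroke extreme (ventral for dv, posterior for ap, pronated for rot)
  occupies ``(1 - a)`` of the period, the return half ``a`` of it, so
  ``a > 0.5`` means a faster power stroke;
* a *rotation hold*: the rotation DOF can be held motionless for a total
  duration ``h`` per cycle, split equally between its two extremes, so the
  blade pitch stays fixed through most of a half-stroke and flips quickly.

Left and right limbs of a pair move in synchrony (straight swimming), so a
full periodic stroke of both limb pairs is described by 26 free values:
2 pairs x 3 DOFs x (min, max, phase) = 18 sinusoid values, plus 6 per-DOF
asymmetries and 2 per-pair rotation holds.  The stroke frequency is fixed at
0.5 Hz and is not a free parameter.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "STROKE_FREQUENCY_HZ",
    "N_STROKE_PARAMS",
    "N_SINUSOID_PARAMS",
    "DOF_NAMES",
    "SinusoidSpec",
    "LimbStroke",
    "StrokeParams",
    "JointRangePreset",
    "load_presets",
    "warp_time",
    "eval_dof",
    "joint_targets",
    "encode",
    "decode",
    "parameter_bounds",
    "neutral_pose",
    "abducted_pose",
]

#: Stroke frequency shared by every sinusoid (Hz).  Period = 2 s.
STROKE_FREQUENCY_HZ = 0.5

N_STROKE_PARAMS = 26
N_SINUSOID_PARAMS = 18

DOF_NAMES = ("dv", "ap", "rot")

# Direction of the power stroke per DOF: -1 means the power extreme is the
# minimum angle (ventral flap, posterior sweep), +1 the maximum (pronation).
_POWER_SIGN = {"dv": -1, "ap": -1, "rot": +1}

LimbPair = Literal["fore", "hind"]
ActiveLimbs = Literal["all", "fore", "hind"]


@dataclass(frozen=True)
class SinusoidSpec:
    """One DOF of one limb pair: a modified sinusoid in degrees."""

    min_angle: float
    max_angle: float
    phase: float  # fraction of the period in [0, 1)
    asymmetry: float = 0.5  # in (0, 1); >0.5 = faster power stroke

    def __post_init__(self):
        if not (self.min_angle <= self.max_angle):
            raise ValueError(
                f"min_angle {self.min_angle} > max_angle {self.max_angle}"
            )
        if not (0.0 < self.asymmetry < 1.0):
            raise ValueError(f"asymmetry must lie in (0,1), got {self.asymmetry}")


@dataclass(frozen=True)
class LimbStroke:
    """Stroke of one limb pair: three DOF sinusoids plus the rotation hold."""

    dorsoventral: SinusoidSpec
    anteroposterior: SinusoidSpec
    rotation: SinusoidSpec
    rotation_hold: float = 0.0  # seconds of motionless rotation per cycle

    def dof(self, name: str) -> SinusoidSpec:
        return {
            "dv": self.dorsoventral,
            "ap": self.anteroposterior,
            "rot": self.rotation,
        }[name]


@dataclass(frozen=True)
class StrokeParams:
    """Full periodic stroke of both limb pairs (26 free values)."""

    fore: LimbStroke
    hind: LimbStroke
    frequency: float = STROKE_FREQUENCY_HZ  # fixed, not a free parameter

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    def limb(self, pair: LimbPair) -> LimbStroke:
        return self.fore if pair == "fore" else self.hind


@dataclass(frozen=True)
class JointRangePreset:
    """Named angle bounds plus neutral/abducted poses, degrees.

    ``bounds[pair][dof] = (lo, hi)``.  The rotation bounds are identical in
    every preset.  The abducted start pose raises the limb to the preset's
    maximum dorsal elevation.
    """

    name: str
    bounds: dict = field(default_factory=dict)
    neutral: dict = field(default_factory=dict)

    def lo(self, pair: LimbPair, dof: str) -> float:
        return self.bounds[pair][dof][0]

    def hi(self, pair: LimbPair, dof: str) -> float:
        return self.bounds[pair][dof][1]


def load_presets(path=None) -> dict[str, JointRangePreset]:
    """Load named joint-range presets from JSON (defaults ship in-package)."""
    if path is None:
        raw = json.loads(
            resources.files("plesioswim.data").joinpath("joint_ranges.json").read_text()
        )
    else:
        with open(path) as fh:
            raw = json.load(fh)
    presets = {}
    for name, spec in raw["presets"].items():
        bounds = {
            pair: {dof: tuple(spec[pair][dof]) for dof in DOF_NAMES}
            for pair in ("fore", "hind")
        }
        presets[name] = JointRangePreset(name=name, bounds=bounds, neutral=raw["neutral"])
    return presets


def neutral_pose(preset: JointRangePreset, pair: LimbPair) -> tuple[float, float, float]:
    """(dv, ap, rot) neutral angles for one limb pair, degrees."""
    n = preset.neutral[pair]
    return (n["dv"], n["ap"], n["rot"])


def abducted_pose(preset: JointRangePreset, pair: LimbPair) -> tuple[float, float, float]:
    """Fully abducted start pose: maximum dorsal elevation, ap/rot neutral."""
    n = preset.neutral[pair]
    return (preset.hi(pair, "dv"), n["ap"], n["rot"])


# ---------------------------------------------------------------------------
# time warping

def warp_time(a: float, t, period: float):
    """Asymmetric piecewise-linear reparameterization of one period.

    Monotone continuous bijection of each period onto itself with fixed
    endpoints: the first half-cycle of the warped time (the sweep toward
    the power-stroke extreme, for a signal starting at the opposite
    extreme) occupies ``(1-a)*period`` of real time, the return half
    ``a*period``, so ``a > 0.5`` gives a faster power stroke.  Reduces to
    the identity at ``a = 0.5``.
    """
    if not (0.0 < a < 1.0):
        raise ValueError(f"asymmetry must lie in (0,1), got {a}")
    x = np.asarray(t, dtype=float) / period
    frac = np.mod(x, 1.0)
    w = np.where(
        frac < (1.0 - a),
        0.5 * frac / (1.0 - a),
        0.5 + 0.5 * (frac - (1.0 - a)) / a,
    )
    out = (np.floor(x) + w) * period
    return out if out.shape else float(out)


def _warp_unit(x, a: float, hold_frac: float):
    """Warped sinusoid argument g(x) on the unit cycle.

    ``x`` is normalized time in [0,1) *after* phase shifting; the returned
    ``g`` feeds ``sin(2*pi*g)`` whose maximum sits at g = 0.25 and minimum at
    g = 0.75.  The maximum plateau is centered at x = 0.25.  ``a`` is the
    fraction of the moving time spent on the ascending (min->max) sweep;
    ``hold_frac`` the fraction of the period spent motionless (split equally
    between the two extremes).
    """
    h = hold_frac
    move = 1.0 - h
    d_desc = move * (1.0 - a)  # descending max->min
    d_asc = move * a           # ascending min->max
    # segment boundaries, starting at the center of the max plateau (x=0.25)
    s = np.mod(x - 0.25, 1.0)
    g = np.empty_like(s)
    b1 = h / 4.0                      # end of first half of max plateau
    b2 = b1 + d_desc                  # end of descending sweep
    b3 = b2 + h / 2.0                 # end of min plateau
    b4 = b3 + d_asc                   # end of ascending sweep (b4 + h/4 = 1)
    m0 = s < b1
    m1 = (s >= b1) & (s < b2)
    m2 = (s >= b2) & (s < b3)
    m3 = (s >= b3) & (s < b4)
    m4 = s >= b4
    g[m0] = 0.25
    if d_desc > 0:
        g[m1] = 0.25 + 0.5 * (s[m1] - b1) / d_desc
    else:
        g[m1] = 0.25
    g[m2] = 0.75
    if d_asc > 0:
        g[m3] = 0.75 + 0.5 * (s[m3] - b3) / d_asc
    else:
        g[m3] = 0.75
    g[m4] = 1.25
    return g


def eval_dof(spec: SinusoidSpec, hold: float, t, period: float, power_sign: int = -1):
    """Angle (degrees) of one DOF at time(s) ``t``.

    With ``hold = 0`` and ``asymmetry = 0.5`` this is exactly
    ``mid + amp*sin(2*pi*(t/period + phase))``.  A positive hold keeps the
    signal flat for ``hold/2`` seconds at each extreme, compressing the two
    sweeps into the remaining ``period - hold``.  ``power_sign`` states which
    extreme the power stroke drives toward (-1 = minimum, +1 = maximum) so
    that ``asymmetry > 0.5`` always shortens the power half-cycle.
    """
    if hold < 0 or hold >= period:
        raise ValueError(f"hold must lie in [0, period), got {hold}")
    mid = 0.5 * (spec.min_angle + spec.max_angle)
    amp = 0.5 * (spec.max_angle - spec.min_angle)
    # a_eff is the fraction of moving time on the ascending sweep; the sweep
    # toward the power extreme must take (1 - asymmetry) of the period.
    a_eff = spec.asymmetry if power_sign < 0 else 1.0 - spec.asymmetry
    x = np.mod(np.asarray(t, dtype=float) / period + spec.phase, 1.0)
    g = _warp_unit(x, a_eff, hold / period)
    out = mid + amp * np.sin(2.0 * np.pi * g)
    return out if out.shape else float(out)


# joint order used throughout the package (12 joint DOFs)
JOINT_ORDER = (
    ("fore", "left"), ("fore", "right"), ("hind", "left"), ("hind", "right")
)


def joint_targets(
    params: StrokeParams,
    t,
    active_limbs: ActiveLimbs = "all",
    preset: JointRangePreset | None = None,
    presets: dict | None = None,
) -> np.ndarray:
    """Target joint angles (degrees) at time ``t``.

    Returns shape ``(..., 12)`` ordered fore-left, fore-right, hind-left,
    hind-right, each (dv, ap, rot).  Left and right limbs share identical
    angle values; the articulated body's mirrored joint axes turn equal
    values into sagittally mirrored motion.  An inactive limb pair is locked
    at its neutral pose.
    """
    if preset is None:
        preset = (presets or load_presets())["medium"]
    t = np.asarray(t, dtype=float)
    out = np.empty(t.shape + (12,))
    for j, (pair, _side) in enumerate(JOINT_ORDER):
        active = active_limbs == "all" or active_limbs == pair
        if active:
            limb = params.limb(pair)
            for k, dof in enumerate(DOF_NAMES):
                spec = limb.dof(dof)
                hold = limb.rotation_hold if dof == "rot" else 0.0
                ang = eval_dof(spec, hold, t, params.period, _POWER_SIGN[dof])
                lo, hi = preset.bounds[pair][dof]
                out[..., 3 * j + k] = np.clip(ang, lo, hi)
        else:
            out[..., 3 * j: 3 * j + 3] = neutral_pose(preset, pair)
    return out


# ---------------------------------------------------------------------------
# flat 26-vector encoding

def encode(params: StrokeParams) -> np.ndarray:
    """Flatten to the canonical 26-vector.

    Layout: [fore dv(min,max,phase), fore ap(...), fore rot(...),
    hind dv/ap/rot likewise] (18 values), then the six asymmetries
    (fore dv, ap, rot, hind dv, ap, rot), then the two rotation holds
    (fore, hind) in seconds.
    """
    v = []
    for pair in ("fore", "hind"):
        limb = params.limb(pair)
        for dof in DOF_NAMES:
            s = limb.dof(dof)
            v += [s.min_angle, s.max_angle, s.phase]
    for pair in ("fore", "hind"):
        limb = params.limb(pair)
        v += [limb.dof(dof).asymmetry for dof in DOF_NAMES]
    v += [params.fore.rotation_hold, params.hind.rotation_hold]
    return np.asarray(v, dtype=float)


def decode(vector: Sequence[float], preset: JointRangePreset,
           warn_on_swap: bool = True) -> StrokeParams:
    """Inverse of :func:`encode`, clamping angles into the preset bounds.

    Angle min/max are clipped into the active preset's range for that DOF;
    if clipping leaves min > max the two are swapped (with a warning unless
    ``warn_on_swap`` is false — optimizers explore such vectors routinely).
    Phases are wrapped into [0,1), asymmetries clipped into (0,1) and holds
    into [0, period).
    """
    v = np.asarray(vector, dtype=float)
    if v.shape != (N_STROKE_PARAMS,):
        raise ValueError(f"expected a {N_STROKE_PARAMS}-vector, got shape {v.shape}")
    period = 1.0 / STROKE_FREQUENCY_HZ
    limbs = {}
    for ip, pair in enumerate(("fore", "hind")):
        specs = {}
        for k, dof in enumerate(DOF_NAMES):
            base = 9 * ip + 3 * k
            lo, hi = preset.bounds[pair][dof]
            mn = float(np.clip(v[base], lo, hi))
            mx = float(np.clip(v[base + 1], lo, hi))
            if mn > mx:
                if warn_on_swap:
                    warnings.warn(
                        f"{pair}/{dof}: min {mn:.2f} > max {mx:.2f} after clamping; swapping",
                        stacklevel=2,
                    )
                mn, mx = mx, mn
            phase = float(np.mod(v[base + 2], 1.0))
            a = float(np.clip(v[18 + 3 * ip + k], 1e-3, 1.0 - 1e-3))
            specs[dof] = SinusoidSpec(mn, mx, phase, a)
        hold = float(np.clip(v[24 + ip], 0.0, np.nextafter(period, 0.0)))
        limbs[pair] = LimbStroke(specs["dv"], specs["ap"], specs["rot"], hold)
    return StrokeParams(fore=limbs["fore"], hind=limbs["hind"])


def parameter_bounds(
    preset: JointRangePreset, active_limbs: ActiveLimbs = "all"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(lower, upper, mask) box bounds for the flat 26-vector.

    ``mask`` flags the coordinates that are free in the given experiment:
    all 26 for ``all``, the 13 belonging to one pair (9 sinusoid values,
    3 asymmetries, 1 hold) otherwise.
    """
    period = 1.0 / STROKE_FREQUENCY_HZ
    lo = np.empty(N_STROKE_PARAMS)
    hi = np.empty(N_STROKE_PARAMS)
    for ip, pair in enumerate(("fore", "hind")):
        for k, dof in enumerate(DOF_NAMES):
            base = 9 * ip + 3 * k
            b_lo, b_hi = preset.bounds[pair][dof]
            lo[base: base + 2] = b_lo
            hi[base: base + 2] = b_hi
            lo[base + 2], hi[base + 2] = 0.0, 1.0
        lo[18 + 3 * ip: 21 + 3 * ip] = 0.05
        hi[18 + 3 * ip: 21 + 3 * ip] = 0.95
        lo[24 + ip], hi[24 + ip] = 0.0, 0.9 * period
    mask = np.zeros(N_STROKE_PARAMS, dtype=bool)
    for ip, pair in enumerate(("fore", "hind")):
        if active_limbs == "all" or active_limbs == pair:
            mask[9 * ip: 9 * ip + 9] = True
            mask[18 + 3 * ip: 21 + 3 * ip] = True
            mask[24 + ip] = True
    return lo, hi, mask
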