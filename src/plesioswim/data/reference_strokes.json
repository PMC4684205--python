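{
  "comment": [
    "Published optimized medium-range stroke parameters (achieved joint",
    "min/max in degrees, per-DOF downstroke/upstroke time asymmetry, and",
    "rotation motionless interval in seconds) for the all-limbs,",
    "forelimbs-only and hindlimbs-only experiments.  Phases are not",
    "published; the dorsoventral flap starts at its dorsal maximum (phase",
    "0.25 under the anchor-at-maximum convention) so motion opens with a",
    "downstroke, and the rotation phase (pronation plateau covering the",
    "downstroke) was fixed once per limb pair by a small grid search over",
    "candidate phases maximizing cycle-2 travel at the desk-scale grid."
  ],
  "medium": {
    "all": {
      "fore": {
        "dv": {
          "min": -39,
          "max": 29,
          "phase": 0.25,
          "asym": 0.64
        },
        "ap": {
          "min": -20,
          "max": -4,
          "phase": 0.25,
          "asym": 0.52
        },
        "rot": {
          "min": -26,
          "max": 41,
          "phase": 0.22,
          "asym": 0.6
        },
        "hold": 1.39
      },
      "hind": {
        "dv": {
          "min": -48,
          "max": 10,
          "phase": 0.25,
          "asym": 0.64
        },
        "ap": {
          "min": -52,
          "max": -10,
          "phase": 0.25,
          "asym": 0.52
        },
        "rot": {
          "min": -12,
          "max": 42,
          "phase": 0.18,
          "asym": 0.61
        },
        "hold": 1.02
      }
    },
    "fore": {
      "fore": {
        "dv": {
          "min": -39,
          "max": 29,
          "phase": 0.25,
          "asym": 0.64
        },
        "ap": {
          "min": -20,
          "max": -1.5,
          "phase": 0.25,
          "asym": 0.58
        },
        "rot": {
          "min": -26,
          "max": 44,
          "phase": 0.22,
          "asym": 0.59
        },
        "hold": 0.56
      }
    },
    "hind": {
      "hind": {
        "dv": {
          "min": -49,
          "max": 13,
          "phase": 0.25,
          "asym": 0.5
        },
        "ap": {
          "min": -45,
          "max": -7,
          "phase": 0.25,
          "asym": 0.57
        },
        "rot": {
          "min": -14,
          "max": 44,
          "phase": 0.18,
          "asym": 0.5
        },
        "hold": 0.94
      }
    }
  }
}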