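{
  "comment": [
    "Named joint-range presets for the four-flippered swimmer, degrees.",
    "Dorsoventral (dv) angles are measured from the horizontal along the",
    "propodial long axis; anteroposterior (ap) angles from a line drawn",
    "perpendicular to the long axis of the body; rotation (rot) is about the",
    "limb long axis with positive = pronation, negative = supination.",
    "The rotation range is identical in every preset. The dv/ap endpoints are",
    "back-derived from the published achieved ranges and their printed",
    "percent-of-available-range values; edit freely, these are config."
  ],
  "presets": {
    "narrow": {
      "fore": {"dv": [-24.0, 30.0], "ap": [-21.0, -11.0], "rot": [-30.0, 45.0]},
      "hind": {"dv": [-32.0, 5.0], "ap": [-57.0, -27.0], "rot": [-30.0, 45.0]}
    },
    "medium": {
      "fore": {"dv": [-40.0, 30.0], "ap": [-33.0, 2.0], "rot": [-30.0, 45.0]},
      "hind": {"dv": [-50.0, 15.0], "ap": [-52.0, -2.0], "rot": [-30.0, 45.0]}
    },
    "wide": {
      "fore": {"dv": [-80.0, 30.0], "ap": [-45.0, 15.0], "rot": [-30.0, 45.0]},
      "hind": {"dv": [-80.0, 30.0], "ap": [-62.0, 9.0], "rot": [-30.0, 45.0]}
    }
  },
  "neutral": {
    "fore": {"dv": -15.0, "ap": -16.0, "rot": 0.0},
    "hind": {"dv": -30.0, "ap": -27.0, "rot": 0.0}
  }
}
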