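{
  "seed": 5,
  "stages": {
    "csp": {"synthetic": {"n_residues": 165, "sites": [24, 33, 49, 118, 124, 137, 160]}},
    "unfolding": {
      "n_boot": 200,
      "samples": [
        {"name": "wild-type", "synthetic": {"Cm": 3.0, "m": 2.4}},
        {"name": "N-less", "synthetic": {"Cm": 2.4, "m": 1.9}},
        {"name": "N-less NTD", "synthetic": {"Cm": 2.6, "m": 1.8}},
        {"name": "N-less CTD", "synthetic": {"Cm": 2.4, "m": 1.9}}
      ]
    },
    "dls": {
      "samples": [
        {"name": "wild-type", "synthetic": {"kd": -3.0}},
        {"name": "N-less", "synthetic": {"kd": -4.0}},
        {"name": "N-less NTD", "synthetic": {"kd": -5.0}},
        {"name": "N-less CTD", "synthetic": {"kd": -5.0}}
      ]
    },
    "trajectory": {"synthetic": {"n_frames": 500}}
  }
}
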