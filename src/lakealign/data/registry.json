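{
  "initial": {
    "olci": {
      "oc2": {"kind": "ocx", "a0": 0.1731, "a1": -3.9630, "a2": -0.5620, "a3": 4.5008, "a4": -3.0020, "sensor": "olci", "algorithm": "oc2"},
      "oc3": {"kind": "ocx", "a0": 0.2521, "a1": -2.2146, "a2": 1.5193, "a3": -0.7702, "a4": -0.4291, "sensor": "olci", "algorithm": "oc3"},
      "gilerson": {"kind": "gilerson", "a": 35.75, "b": -19.30, "c": 1.124},
      "gons05": {"kind": "gons05", "p": 1.06, "a_chl_star": 0.025, "aw665": 0.40, "aw709": 0.70, "aw779": 2.71, "k_scatter": 0.6, "k_gamma": 0.082}
    },
    "msi": {
      "oc2": {"kind": "ocx", "a0": 0.2389, "a1": -1.9369, "a2": 1.7627, "a3": -3.0777, "a4": -0.1054, "sensor": "msi", "algorithm": "oc2"},
      "oc3": {"kind": "ocx", "a0": 0.2521, "a1": -2.2146, "a2": 1.5193, "a3": -0.7702, "a4": -0.4291, "sensor": "msi", "algorithm": "oc3"},
      "gilerson": {"kind": "gilerson", "a": 35.75, "b": -19.30, "c": 1.124},
      "gons05": {"kind": "gons05", "p": 1.06, "a_chl_star": 0.016, "aw665": 0.40, "aw709": 0.70, "aw779": 2.71, "k_scatter": 0.6, "k_gamma": 0.082}
    }
  },
  "tuned": {
    "msi": {
      "oc2": {"kind": "ocx", "a0": 0.3818, "a1": -4.9640, "a2": -0.9966, "a3": 7.3857, "a4": -31.5261, "sensor": "msi", "algorithm": "oc2"},
      "oc3": {"kind": "ocx", "a0": 0.3121, "a1": -1.7612, "a2": 2.9117, "a3": 3.2944, "a4": -28.3593, "sensor": "msi", "algorithm": "oc3"},
      "gilerson": {"kind": "gilerson", "a": 9.3803, "b": -3.3763, "c": 1.7304},
      "gons05": {"kind": "gons05", "p": 1.0624, "a_chl_star": 0.0192, "aw665": 0.40, "aw709": 0.70, "aw779": 2.71, "k_scatter": 0.6, "k_gamma": 0.082}
    }
  },
  "turbidity_calibration": {
    "msi": {
      "b665": {"kind": "linear", "gain": 0.882, "offset": -0.024},
      "b708": {"kind": "linear", "gain": 0.868, "offset": 0.087},
      "b778": {"kind": "linear", "gain": 0.843, "offset": -0.333},
      "b865": {"kind": "linear", "gain": 0.990, "offset": -0.008}
    }
  },
  "ratio_scaling": {
    "msi": {
      "oc2": {"kind": "linear", "gain": 1.442, "offset": -0.51}
    }
  }
}
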