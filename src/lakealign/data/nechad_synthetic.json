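{
  "_comment": "SYNTHETIC fixture: per-band Nechad A (FNU) and C (dimensionless) constants with realistic magnitudes (amplitude growing, asymptote ~0.17-0.21, toward the NIR) for testing and simulation. These are NOT values from any calibration campaign; real applications must supply their own per-band look-up table.",
  "nechad": {
    "shared": {
      "b665": {"kind": "nechad", "A": 282.95, "C": 0.1728, "band": "b665"},
      "b708": {"kind": "nechad", "A": 415.29, "C": 0.1875, "band": "b708"},
      "b778": {"kind": "nechad", "A": 1559.52, "C": 0.1978, "band": "b778"},
      "b865": {"kind": "nechad", "A": 2971.93, "C": 0.2112, "band": "b865"}
    }
  }
}
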