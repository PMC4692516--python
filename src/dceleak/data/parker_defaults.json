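{
  "A1": 0.809,
  "A2": 0.330,
  "T1g": 0.17046,
  "T2g": 0.365,
  "sigma1": 0.0563,
  "sigma2": 0.132,
  "alpha1": 0.35,
  "alpha2": 0.70,
  "beta1": 0.34657359027997264,
  "beta2": 0.017328679513998632,
  "s": 38.078,
  "tau": 0.483,
  "Hct": 0.45
}
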