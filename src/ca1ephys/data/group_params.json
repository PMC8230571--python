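{
  "WT-1m":  {"Rm": 29400, "e_pas": -88.28, "gbar": 1.57e-5, "Vl_half": -89.85, "kl": -12.48, "Vt_half": -83.43, "a0t": 3.02e-3, "zetat": 5.42, "gmt": 0.437},
  "AD-1m":  {"Rm": 29400, "e_pas": -86.18, "gbar": 1.55e-5, "Vl_half": -88.73, "kl": -13.08, "Vt_half": -72.64, "a0t": 3.00e-3, "zetat": 4.47, "gmt": 0.181},
  "WT-4m":  {"Rm": 21100, "e_pas": -89.68, "gbar": 1.39e-5, "Vl_half": -99.94, "kl": -11.28, "Vt_half": -89.72, "a0t": 2.00e-3, "zetat": 4.93, "gmt": 0.557},
  "AD-4m":  {"Rm": 20700, "e_pas": -92.29, "gbar": 2.47e-5, "Vl_half": -93.86, "kl": -18.92, "Vt_half": -89.85, "a0t": 3.11e-3, "zetat": 4.96, "gmt": 0.582},
  "WT-10m": {"Rm": 28200, "e_pas": -87.48, "gbar": 1.55e-5, "Vl_half": -80.86, "kl": -10.00, "Vt_half": -76.85, "a0t": 3.10e-3, "zetat": 2.22, "gmt": 0.439},
  "AD-10m": {"Rm": 26400, "e_pas": -88.61, "gbar": 2.35e-5, "Vl_half": -81.21, "kl": -15.62, "Vt_half": -82.22, "a0t": 3.59e-3, "zetat": 5.00, "gmt": 0.514}
}
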