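{
  "yields": {
    "e_aq": 3.8951593638329505,
    "OH_r": 5.759999999994064,
    "H_r": 0.62,
    "H2": 0.4,
    "H2O2": 0.5,
    "H3O_p": 4.395159363832951,
    "OH_m": 0.5
  },
  "objective": 0.004850054716447313,
  "residuals": {
    "depleted_o2_um": -0.09473358220982994,
    "g_minus_o2": -0.026862411234741534
  },
  "targets": {
    "depleted_o2_um": 13.6,
    "g_minus_o2": 4.0
  },
  "bounds_frac": 0.2,
  "success": true,
  "message": "`gtol` termination condition is satisfied."
}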