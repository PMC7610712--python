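{
  "nu": 0.03788079525207495,
  "beta": 4.386786663019358,
  "eta_E": 0.7669466469381565,
  "eta_I": 0.2538641178139396,
  "w_EE": 2.0131434884237773,
  "w_IE": 2.033357279349347,
  "w_EI": 1.0684687233093095,
  "zeta": 0.028608446726601254,
  "dE0": 0.005000000000000001,
  "label": "patientB"
}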