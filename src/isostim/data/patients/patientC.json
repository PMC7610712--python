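{
  "nu": 0.03220741751054719,
  "beta": 2.2189156565607666,
  "eta_E": 1.8402514217552122,
  "eta_I": 0.6298039517950367,
  "w_EE": 2.8850073072847047,
  "w_IE": 3.276987632647606,
  "w_EI": 1.7616268315721013,
  "zeta": 0.1027961821248903,
  "dE0": 0.005000000000000001,
  "label": "patientC"
}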