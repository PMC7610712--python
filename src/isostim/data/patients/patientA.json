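{
  "nu": 0.028692841340520456,
  "beta": 3.067982290527537,
  "eta_E": 1.4996303724167832,
  "eta_I": 0.4930738133428718,
  "w_EE": 3.01050872625679,
  "w_IE": 5.830019401757464,
  "w_EI": 0.7684848161545204,
  "zeta": 0.04675360520024157,
  "dE0": 0.005000000000000001,
  "label": "patientA"
}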