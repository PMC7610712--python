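{
  "patients": [
    {
      "label": "patientA",
      "file": "patientA.json",
      "seed": 1,
      "sigma": -4.514690542121002,
      "omega": 31.808161330484968,
      "freq_hz": 5.062426106411161,
      "x_star": [
        0.2519862505843545,
        0.27665138014051455
      ],
      "orbit_radius": 0.05000000000000001,
      "grid": {
        "e_min": 0.156,
        "e_max": 0.419,
        "i_min": 0.243,
        "i_max": 0.339,
        "de": 0.001,
        "di": 0.001
      }
    },
    {
      "label": "patientB",
      "file": "patientB.json",
      "seed": 3,
      "sigma": -0.7701242123295367,
      "omega": 30.64793955918752,
      "freq_hz": 4.877771076426338,
      "x_star": [
        0.6736023256882064,
        0.47106546275900124
      ],
      "orbit_radius": 0.05000000000000001,
      "grid": {
        "e_min": 0.556,
        "e_max": 0.763,
        "i_min": 0.38,
        "i_max": 0.539,
        "de": 0.001,
        "di": 0.001
      }
    },
    {
      "label": "patientC",
      "file": "patientC.json",
      "seed": 4,
      "sigma": -7.712011042830587,
      "omega": 30.07790407653625,
      "freq_hz": 4.787047111624614,
      "x_star": [
        0.37679996666208,
        0.6573349111183046
      ],
      "orbit_radius": 0.05000000000000001,
      "grid": {
        "e_min": 0.271,
        "e_max": 0.512,
        "i_min": 0.585,
        "i_max": 0.74,
        "de": 0.001,
        "di": 0.001
      }
    }
  ]
}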