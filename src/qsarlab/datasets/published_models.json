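[
  {
    "name": "model_1",
    "descriptors": ["MATS4e", "GATS5e", "SpMax4_Bhs", "RDF150u"],
    "coefficients": [4.888518176, -2.570261057, -1.514002889, 0.086137333],
    "intercept": 13.256220911
  },
  {
    "name": "model_2",
    "descriptors": ["ALogp2", "MATS4e", "GATS5e", "RDF150u"],
    "coefficients": [-0.018183153, 4.669978294, -1.245497827, 0.065416696],
    "intercept": 6.326485838
  },
  {
    "name": "model_3",
    "descriptors": ["ALogp2", "MATS4e", "GATS4e", "RDF150u"],
    "coefficients": [-0.021417358, 2.673511925, -1.523695399, 0.061648777],
    "intercept": 6.593640317
  },
  {
    "name": "model_4",
    "descriptors": ["MATS4e", "GATS5e", "RDF150u", "P1m"],
    "coefficients": [4.242442241, -1.572590496, 0.065174802, -0.392069439],
    "intercept": 6.739118905
  }
]
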