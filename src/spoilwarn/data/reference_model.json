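{
  "schema_version": 1,
  "provenance": "published SA-PLS apple spoilage early-warning reference model",
  "variable_indices": [228, 309, 622, 726, 1064, 1126, 1188, 1526, 1538, 1861,
                       1889, 1894, 1974, 2001, 2159, 2163, 2274, 2561, 2758, 2965],
  "coefficients": [0.3264, 0.3708, 0.0248, 0.0363, -0.0008, -0.0005, -0.0014,
                   0.4734, 0.3338, 0.0248, -0.0136, -0.0118, -0.0132, 0.3407,
                   -1.9581, 0.3719, 0.5173, -1.9010, 0.0013, -0.0009],
  "intercept": 38.9899,
  "grade_bands": [
    {"label": "fresh", "lower": -Infinity, "upper": 2.5, "nominal_range": [1, 2]},
    {"label": "mild spoilage", "lower": 2.5, "upper": 4.5, "nominal_range": [3, 4]},
    {"label": "medium spoilage", "lower": 4.5, "upper": 6.5, "nominal_range": [5, 6]},
    {"label": "severe spoilage", "lower": 6.5, "upper": Infinity, "nominal_range": [7, 8]}
  ]
}
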