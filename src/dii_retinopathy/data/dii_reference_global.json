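{
 "mode": "raw",
 "source": "Global reference means/SDs and inflammatory effect scores for the 27 food parameters available in 24-h recall data, transcribed (approximate) from the published dietary inflammatory index development methodology (Shivappa et al. 2014, Public Health Nutrition 17:1689-1696). Transcription is illustrative; analyses should pass their own vetted table.",
 "components": [
  {"name": "alcohol", "unit": "g", "global_mean": 13.98, "global_sd": 3.72, "effect_score": -0.278},
  {"name": "protein", "unit": "g", "global_mean": 79.4, "global_sd": 13.9, "effect_score": 0.021},
  {"name": "fiber", "unit": "g", "global_mean": 18.8, "global_sd": 4.9, "effect_score": -0.663},
  {"name": "beta_carotene", "unit": "ug", "global_mean": 3718.0, "global_sd": 1720.0, "effect_score": -0.584},
  {"name": "cholesterol", "unit": "mg", "global_mean": 279.4, "global_sd": 51.2, "effect_score": 0.11},
  {"name": "carbohydrate", "unit": "g", "global_mean": 272.2, "global_sd": 40.0, "effect_score": 0.097},
  {"name": "energy", "unit": "kcal", "global_mean": 2056.0, "global_sd": 338.0, "effect_score": 0.18},
  {"name": "total_fat", "unit": "g", "global_mean": 71.4, "global_sd": 19.4, "effect_score": 0.298},
  {"name": "n3_fatty_acids", "unit": "g", "global_mean": 1.06, "global_sd": 1.06, "effect_score": -0.436},
  {"name": "n6_fatty_acids", "unit": "g", "global_mean": 10.8, "global_sd": 7.5, "effect_score": -0.159},
  {"name": "pufa", "unit": "g", "global_mean": 13.88, "global_sd": 3.76, "effect_score": -0.337},
  {"name": "mufa", "unit": "g", "global_mean": 27.0, "global_sd": 6.1, "effect_score": -0.009},
  {"name": "saturated_fat", "unit": "g", "global_mean": 28.6, "global_sd": 8.0, "effect_score": 0.373},
  {"name": "thiamin", "unit": "mg", "global_mean": 1.7, "global_sd": 0.66, "effect_score": -0.098},
  {"name": "magnesium", "unit": "mg", "global_mean": 310.1, "global_sd": 139.4, "effect_score": -0.484},
  {"name": "zinc", "unit": "mg", "global_mean": 9.84, "global_sd": 2.19, "effect_score": -0.313},
  {"name": "selenium", "unit": "ug", "global_mean": 67.0, "global_sd": 25.1, "effect_score": -0.191},
  {"name": "iron", "unit": "mg", "global_mean": 13.35, "global_sd": 3.71, "effect_score": 0.032},
  {"name": "riboflavin", "unit": "mg", "global_mean": 1.7, "global_sd": 0.79, "effect_score": -0.068},
  {"name": "folic_acid", "unit": "ug", "global_mean": 273.0, "global_sd": 70.7, "effect_score": -0.19},
  {"name": "vitamin_a", "unit": "RE", "global_mean": 983.9, "global_sd": 518.6, "effect_score": -0.401},
  {"name": "vitamin_b6", "unit": "mg", "global_mean": 1.47, "global_sd": 0.74, "effect_score": -0.365},
  {"name": "vitamin_b12", "unit": "ug", "global_mean": 5.15, "global_sd": 2.7, "effect_score": 0.106},
  {"name": "vitamin_c", "unit": "mg", "global_mean": 118.2, "global_sd": 43.46, "effect_score": -0.424},
  {"name": "vitamin_d", "unit": "ug", "global_mean": 6.26, "global_sd": 2.21, "effect_score": -0.446},
  {"name": "vitamin_e", "unit": "mg", "global_mean": 8.73, "global_sd": 1.49, "effect_score": -0.419},
  {"name": "caffeine", "unit": "g", "global_mean": 8.05, "global_sd": 6.67, "effect_score": -0.11},
  {"name": "niacin", "unit": "mg", "global_mean": 25.9, "global_sd": 11.77, "effect_score": -0.246}
 ]
}
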