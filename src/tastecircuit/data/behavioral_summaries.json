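{
  "groups": {"CW": 26, "AN": 26, "BN": 25},
  "variables": {
    "age_years":              {"CW": [24.39, 3.49], "AN": [23.23, 5.26], "BN": [24.64, 4.22]},
    "body_mass_index":        {"CW": [21.61, 1.21], "AN": [16.23, 1.09], "BN": [23.56, 5.89]},
    "novelty_seeking":        {"CW": [18.42, 5.27], "AN": [13.89, 6.02], "BN": [22.20, 6.70]},
    "harm_avoidance":         {"CW": [10.08, 4.74], "AN": [23.65, 5.94], "BN": [22.48, 5.93]},
    "reward_dependence":      {"CW": [16.54, 3.47], "AN": [15.04, 3.04], "BN": [15.60, 4.57]},
    "depression_bdi":         {"CW": [1.27, 1.28],  "AN": [21.27, 12.94], "BN": [22.68, 14.58]},
    "drive_for_thinness":     {"CW": [2.42, 3.51],  "AN": [19.96, 5.98], "BN": [21.92, 4.65]},
    "bulimia_edi3":           {"CW": [0.92, 1.23],  "AN": [3.89, 4.97],  "BN": [20.00, 5.43]},
    "body_dissatisfaction":   {"CW": [4.62, 4.26],  "AN": [24.31, 8.99], "BN": [30.44, 7.58]},
    "sensitivity_to_reward":  {"CW": [5.00, 2.95],  "AN": [6.69, 3.71],  "BN": [7.56, 3.38]},
    "sensitivity_to_punishment": {"CW": [4.42, 2.69], "AN": [12.96, 3.85], "BN": [12.56, 3.80]},
    "state_anxiety":          {"CW": [26.46, 4.82], "AN": [55.23, 11.95], "BN": [50.52, 13.14]},
    "trait_anxiety":          {"CW": [28.04, 4.29], "AN": [56.39, 11.98], "BN": [58.80, 9.75]},
    "sucrose_pleasantness":   {"CW": [4.92, 2.43],  "AN": [4.58, 2.32],  "BN": [5.88, 2.57]},
    "sucrose_sweetness":      {"CW": [8.23, 0.82],  "AN": [8.31, 1.19],  "BN": [8.28, 0.98]},
    "education_years":        {"CW": [16.52, 1.92], "AN": [14.39, 2.25], "BN": [15.77, 3.09]}
  }
}
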