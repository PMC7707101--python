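{
  "threshold_policy": {
    "wbc_cutoff": 11.0,
    "neutrophilia_abs_cutoff": 7.9,
    "neutrophilia_pct_cutoff": 75.0,
    "crp_cutoff": 20.0,
    "temp_cutoff": 38.5
  },
  "scores": [
    {
      "name": "alvarado",
      "items": [
        ["tenderness_rlq", 2],
        ["rebound_tenderness", 1],
        ["wbc_elevated", 2],
        ["nausea_vomiting", 1],
        ["anorexia", 1],
        ["migration_of_pain", 1],
        ["fever", 1],
        ["neutrophilia", 1]
      ],
      "positivity_cutoff": 5
    },
    {
      "name": "pas",
      "items": [
        ["tenderness_rlq", 2],
        ["cough_hop_tenderness", 2],
        ["wbc_elevated", 1],
        ["nausea_vomiting", 1],
        ["anorexia", 1],
        ["migration_of_pain", 1],
        ["fever", 1],
        ["neutrophilia", 1]
      ],
      "positivity_cutoff": 6
    },
    {
      "name": "tzanakis",
      "items": [
        ["tenderness_rlq", 4],
        ["rebound_tenderness", 3],
        ["wbc_elevated", 2],
        ["us_appendicitis", 6]
      ],
      "positivity_cutoff": 8
    },
    {
      "name": "has",
      "items": [
        ["tenderness_rlq", 1],
        ["rebound_tenderness", 1],
        ["us_appendicitis", 1],
        ["continuous_pain", 1]
      ],
      "positivity_cutoff": 3
    },
    {
      "name": "modified_has",
      "items": [
        ["tenderness_rlq", 1],
        ["rebound_tenderness", 1],
        ["wbc_elevated", 1],
        ["crp_elevated", 1],
        ["us_appendicitis", 1]
      ],
      "positivity_cutoff": 3
    },
    {
      "name": "ai_score",
      "items": [
        ["rebound_tenderness", 1],
        ["wbc_elevated", 1],
        ["crp_elevated", 1],
        ["us_appendicitis", 1]
      ],
      "positivity_cutoff": 2
    }
  ]
}
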