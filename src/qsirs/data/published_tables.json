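{
  "description": "Published score-vs-death 2x2 counts and the derived quantities printed alongside them, for an emergency-surgery cohort of n=118 with 11 deaths at 30 days.",
  "n": 118,
  "deaths": 11,
  "published_mortality_percent": "9.3",
  "scores": [
    {
      "score_name": "QSOFA",
      "tp": 4, "fp": 9, "fn": 7, "tn": 98,
      "published_or": 6.2,
      "published_or_ci": [1.5, 25.3],
      "published_p": 0.01,
      "published_sens": "36.3",
      "published_spec": "91.5",
      "published_ppv": "30.7",
      "published_npv": "93.3",
      "or_ci_asserted": true
    },
    {
      "score_name": "SIRS",
      "tp": 9, "fp": 38, "fn": 2, "tn": 69,
      "published_or": 8.0,
      "published_or_ci": [1.8, 56.9],
      "published_p": 0.003,
      "published_sens": "81.8",
      "published_spec": "64.4",
      "published_ppv": "19.1",
      "published_npv": "97.1",
      "or_ci_asserted": false
    },
    {
      "score_name": "QSIRS",
      "tp": 10, "fp": 49, "fn": 1, "tn": 58,
      "published_or": 11.8,
      "published_or_ci": [1.4, 95.7],
      "published_p": 0.004,
      "published_sens": "90.9",
      "published_spec": "54.2",
      "published_ppv": "16.9",
      "published_npv": "98.3",
      "or_ci_asserted": true
    }
  ]
}
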