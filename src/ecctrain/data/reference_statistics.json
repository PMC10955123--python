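{
  "description": "Published omnibus and post-hoc test statistics of the eccentric shoulder-training RCT, used as worked examples for the effect-size identities.",
  "n_intervention_functional": 14,
  "n_control_functional": 11,
  "manova": [
    {"name": "strength_time", "wilks_lambda": 0.699, "F": 4.74, "df": [2, 22], "p": 0.019, "partial_eta_sq": 0.301},
    {"name": "strength_time_by_mode", "wilks_lambda": 0.699, "F": 4.74, "df": [2, 22], "p": 0.019, "partial_eta_sq": 0.301},
    {"name": "strength_time_by_speed", "wilks_lambda": 0.691, "F": 4.92, "df": [2, 22], "p": 0.017, "partial_eta_sq": 0.309},
    {"name": "strength_time_by_group", "wilks_lambda": 0.832, "F": 4.74, "df": [2, 22], "p": 0.132, "partial_eta_sq": 0.168},
    {"name": "supraspinatus_interaction", "wilks_lambda": 0.492, "F": 5.86, "df": [3, 17], "p": 0.006, "partial_eta_sq": 0.508},
    {"name": "infraspinatus_interaction", "wilks_lambda": 0.281, "F": 9.38, "df": [3, 11], "p": 0.002, "partial_eta_sq": 0.719}
  ],
  "anova": [
    {"name": "ecc_peak_30_interaction", "F": 3.628, "df": [1, 23], "p": 0.035, "partial_eta_sq": 0.136},
    {"name": "strength_time_main", "F": 4.82, "df": [1, 23], "p": 0.038, "partial_eta_sq": 0.173},
    {"name": "supraspinatus_fl", "F": 3.37, "df": [1, 19], "p": 0.041, "partial_eta_sq": 0.151},
    {"name": "supraspinatus_fa", "F": 3.92, "df": [1, 19], "p": 0.062, "partial_eta_sq": 0.171},
    {"name": "infraspinatus_fl", "F": 4.17, "df": [1, 13], "p": 0.031, "partial_eta_sq": 0.243},
    {"name": "infraspinatus_fa", "F": 10.25, "df": [1, 13], "p": 0.007, "partial_eta_sq": 0.441}
  ]
}
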