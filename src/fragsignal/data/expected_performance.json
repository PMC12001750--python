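{
  "note": "Per-assay and per-combination detected counts among the 40 advanced-adenoma cases, overall and by mutually exclusive subgroup (high-grade dysplasia; >=2 cm; >=1 to <2 cm), with control false positives out of 32. Derived by re-scoring the published per-case score table at thresholds 0.78/0.71/0.96 in printed_rounded mode.",
  "subgroup_sizes": {"hgd": 8, "ge2cm": 19, "ge1lt2cm": 13},
  "detected": {
    "signal":                {"all": 9,  "hgd": 1, "ge2cm": 5, "ge1lt2cm": 3, "fp": 0},
    "protein17":             {"all": 5,  "hgd": 3, "ge2cm": 1, "ge1lt2cm": 1, "fp": 0},
    "gas":                   {"all": 11, "hgd": 2, "ge2cm": 6, "ge1lt2cm": 3, "fp": 2},
    "signal+protein17":      {"all": 12, "hgd": 4, "ge2cm": 5, "ge1lt2cm": 3, "fp": 0},
    "signal+gas":            {"all": 13, "hgd": 2, "ge2cm": 8, "ge1lt2cm": 3, "fp": 2},
    "protein17+gas":         {"all": 14, "hgd": 5, "ge2cm": 6, "ge1lt2cm": 3, "fp": 2},
    "signal+protein17+gas":  {"all": 16, "hgd": 5, "ge2cm": 8, "ge1lt2cm": 3, "fp": 2}
  },
  "comparators": {
    "fit":              {"detected": 15, "by_group": [4, 8, 3], "specificity": 96.0},
    "mt_sdna":          {"detected": 24, "by_group": [6, 13, 5], "specificity": 90.0},
    "mt_sdna_next_gen": {"detected": 24, "by_group": [6, 13, 5], "specificity": 92.7}
  }
}
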