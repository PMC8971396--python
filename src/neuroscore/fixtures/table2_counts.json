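{
  "description": "Per-score-level gene counts by OMIM outcome category. total = cns + non_cns + no_phenotype; absent_from_omim is the subset of no_phenotype genes with no OMIM entry at all.",
  "levels": {
    "0": {"total": 10461, "cns": 715, "non_cns": 1389, "no_phenotype": 8357, "absent_from_omim": 2734},
    "1": {"total": 3290, "cns": 489, "non_cns": 409, "no_phenotype": 2392, "absent_from_omim": 453},
    "2": {"total": 3407, "cns": 603, "non_cns": 284, "no_phenotype": 2520, "absent_from_omim": 644},
    "3": {"total": 1079, "cns": 241, "non_cns": 91, "no_phenotype": 747, "absent_from_omim": 135},
    "4": {"total": 447, "cns": 121, "non_cns": 29, "no_phenotype": 297, "absent_from_omim": 11},
    "5": {"total": 75, "cns": 58, "non_cns": 3, "no_phenotype": 14, "absent_from_omim": 2}
  }
}
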