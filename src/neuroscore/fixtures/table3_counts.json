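{
  "description": "Counts of CNVs by the maximum score level of any contained gene, per cohort and loss/gain stratum. NA = CNVs whose genes are all unscorable.",
  "counts": {
    "loss": {
      "case": {"5": 5, "4": 52, "3": 78, "2": 115, "1": 149, "0": 435, "NA": 1},
      "control": {"5": 0, "4": 9, "3": 7, "2": 365, "1": 307, "0": 1501, "NA": 358}
    },
    "gain": {
      "case": {"5": 18, "4": 102, "3": 176, "2": 288, "1": 261, "0": 509, "NA": 3},
      "control": {"5": 1, "4": 25, "3": 52, "2": 354, "1": 300, "0": 746, "NA": 384}
    }
  }
}
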