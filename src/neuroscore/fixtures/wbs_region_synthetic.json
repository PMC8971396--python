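{
  "description": "7q11.23 Williams-Beuren region gene list. Per-gene scores are SYNTHETIC stand-ins constructed to reproduce the region's summary counts (25 genes, 15 scored, 6 high scoring); only those counts and the six high-scoring gene identities are meaningful.",
  "region": "7q11.23",
  "synthetic_scores": true,
  "expected": {"total_genes": 25, "scored_genes": 15, "high_scoring": 6},
  "genes": [
    {"symbol": "FKBP6", "score": 0},
    {"symbol": "FZD9", "score": 2},
    {"symbol": "BAZ1B", "score": 3},
    {"symbol": "BCL7B", "score": 1},
    {"symbol": "TBL2", "score": 1},
    {"symbol": "MLXIPL", "score": 2},
    {"symbol": "VPS37D", "score": 0},
    {"symbol": "DNAJC30", "score": 0},
    {"symbol": "BUD23", "score": 1},
    {"symbol": "STX1A", "score": 4},
    {"symbol": "ABHD11", "score": 0},
    {"symbol": "CLDN3", "score": 0},
    {"symbol": "CLDN4", "score": 0},
    {"symbol": "METTL27", "score": 0},
    {"symbol": "TMEM270", "score": null},
    {"symbol": "ELN", "score": 1},
    {"symbol": "LIMK1", "score": 3},
    {"symbol": "EIF4H", "score": 3},
    {"symbol": "LAT2", "score": 1},
    {"symbol": "RFC2", "score": 2},
    {"symbol": "CLIP2", "score": 3},
    {"symbol": "GTF2IRD1", "score": 2},
    {"symbol": "GTF2I", "score": 4},
    {"symbol": "NCF1", "score": null},
    {"symbol": "GTF2IRD2", "score": null}
  ]
}
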