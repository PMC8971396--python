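{
  "description": "22q11.2 recurrent deletion/duplication region gene list with A-B, B-D and D-F breakpoint segments. Per-gene scores are SYNTHETIC stand-ins constructed to reproduce the region's summary counts (64 genes, 38 scored, 8 high scoring; MAPK1 scored 4 in D-F; every segment has at least one high-scoring gene); only those counts and MAPK1's score are meaningful.",
  "region": "22q11.2",
  "synthetic_scores": true,
  "expected": {"total_genes": 64, "scored_genes": 38, "high_scoring": 8},
  "genes": [
    {"symbol": "PRODH", "segment": "A-B", "score": 1},
    {"symbol": "DGCR2", "segment": "A-B", "score": 1},
    {"symbol": "DGCR11", "segment": "A-B", "score": null},
    {"symbol": "TSSK2", "segment": "A-B", "score": 0},
    {"symbol": "GSC2", "segment": "A-B", "score": 0},
    {"symbol": "SLC25A1", "segment": "A-B", "score": 2},
    {"symbol": "CLTCL1", "segment": "A-B", "score": 1},
    {"symbol": "HIRA", "segment": "A-B", "score": 2},
    {"symbol": "MRPL40", "segment": "A-B", "score": 0},
    {"symbol": "C22orf39", "segment": "A-B", "score": 0},
    {"symbol": "UFD1", "segment": "A-B", "score": 2},
    {"symbol": "CDC45", "segment": "A-B", "score": 1},
    {"symbol": "CLDN5", "segment": "A-B", "score": 1},
    {"symbol": "SEPT5", "segment": "A-B", "score": 0},
    {"symbol": "GP1BB", "segment": "A-B", "score": 0},
    {"symbol": "TBX1", "segment": "A-B", "score": 3},
    {"symbol": "GNB1L", "segment": "A-B", "score": 2},
    {"symbol": "TXNRD2", "segment": "A-B", "score": 1},
    {"symbol": "COMT", "segment": "A-B", "score": 3},
    {"symbol": "ARVCF", "segment": "A-B", "score": 1},
    {"symbol": "TANGO2", "segment": "A-B", "score": 0},
    {"symbol": "DGCR8", "segment": "A-B", "score": 3},
    {"symbol": "TRMT2A", "segment": "A-B", "score": 0},
    {"symbol": "RANBP1", "segment": "A-B", "score": 2},
    {"symbol": "ZDHHC8", "segment": "B-D", "score": 2},
    {"symbol": "RTN4R", "segment": "B-D", "score": 1},
    {"symbol": "DGCR6L", "segment": "B-D", "score": null},
    {"symbol": "GGT2", "segment": "B-D", "score": null},
    {"symbol": "RIMBP3", "segment": "B-D", "score": null},
    {"symbol": "ZNF74", "segment": "B-D", "score": 1},
    {"symbol": "SCARF2", "segment": "B-D", "score": 0},
    {"symbol": "KLHL22", "segment": "B-D", "score": 0},
    {"symbol": "MED15", "segment": "B-D", "score": 2},
    {"symbol": "PI4KA", "segment": "B-D", "score": 3},
    {"symbol": "SERPIND1", "segment": "B-D", "score": 0},
    {"symbol": "SNAP29", "segment": "B-D", "score": 3},
    {"symbol": "CRKL", "segment": "B-D", "score": 4},
    {"symbol": "AIFM3", "segment": "B-D", "score": 0},
    {"symbol": "LZTR1", "segment": "B-D", "score": 2},
    {"symbol": "THAP7", "segment": "B-D", "score": 1},
    {"symbol": "P2RX6", "segment": "D-F", "score": 0},
    {"symbol": "SLC7A4", "segment": "D-F", "score": 0},
    {"symbol": "LRRC74B", "segment": "D-F", "score": null},
    {"symbol": "GNAZ", "segment": "D-F", "score": 2},
    {"symbol": "RAB36", "segment": "D-F", "score": 1},
    {"symbol": "RSPH14", "segment": "D-F", "score": null},
    {"symbol": "UPB1", "segment": "D-F", "score": 1},
    {"symbol": "GUCD1", "segment": "D-F", "score": 1},
    {"symbol": "SNRPD3", "segment": "D-F", "score": 1},
    {"symbol": "GGT5", "segment": "D-F", "score": 0},
    {"symbol": "SUSD2", "segment": "D-F", "score": 1},
    {"symbol": "CABIN1", "segment": "D-F", "score": 2},
    {"symbol": "DDT", "segment": "D-F", "score": 0},
    {"symbol": "GSTT2", "segment": "D-F", "score": 0},
    {"symbol": "MIF", "segment": "D-F", "score": 1},
    {"symbol": "SLC2A11", "segment": "D-F", "score": 1},
    {"symbol": "SEC14L2", "segment": "D-F", "score": 1},
    {"symbol": "MAPK1", "segment": "D-F", "score": 4},
    {"symbol": "PPIL2", "segment": "D-F", "score": 1},
    {"symbol": "YPEL1", "segment": "D-F", "score": 0},
    {"symbol": "PPM1F", "segment": "D-F", "score": 2},
    {"symbol": "TOP3B", "segment": "D-F", "score": 3},
    {"symbol": "VPREB1", "segment": "D-F", "score": 0},
    {"symbol": "ZNF280B", "segment": "D-F", "score": null}
  ]
}
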