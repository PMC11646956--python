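{
  "pathways": {
    "tca": {
      "name": "Citrate cycle (TCA cycle)",
      "compounds": ["C001", "C002", "C003", "C004", "C005", "C006"]
    },
    "glycolysis": {
      "name": "Glycolysis / Gluconeogenesis",
      "compounds": ["C006", "C007", "C008"]
    },
    "amino_acid": {
      "name": "Alanine and glutamine metabolism",
      "compounds": ["C009", "C010"]
    },
    "fatty_acid": {
      "name": "Fatty acid biosynthesis",
      "compounds": ["C011", "C012"]
    }
  },
  "reference_universe": [
    "C001", "C002", "C003", "C004", "C005", "C006",
    "C007", "C008", "C009", "C010", "C011", "C012"
  ]
}
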