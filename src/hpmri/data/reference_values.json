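{
  "comment": "Published Spearman rank correlations reported for the reference cohort; used by the reproduction report for pass/fail checks.",
  "tolerance": 0.02,
  "correlations": {
    "lactateSNR~meanADC": -0.69,
    "lactateSNR~pctGP4": 0.65,
    "pctGP4~meanADC": -0.62,
    "totalCarbonSNR~pyruvateSNR": 0.90
  }
}
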