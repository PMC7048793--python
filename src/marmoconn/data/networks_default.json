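{
  "Pri": ["A3a", "A3b", "A4ab", "A4c"],
  "HOSom": ["A6DC", "A6M", "A6Va", "A24d", "PF"],
  "VisM": ["LIP", "VIP", "PEc", "A8aV", "A8C"],
  "CON": ["A8aD", "A6DR", "PGM", "A23b", "OPt", "PG"],
  "APEX": ["A10", "A23a", "TPO", "PGa-IPa", "TE3"]
}
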