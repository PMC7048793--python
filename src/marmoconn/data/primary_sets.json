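{
  "default": ["V1", "A3a", "A3b", "AuA1", "AuR", "AuRT", "A4ab", "A4c"],
  "functional_sensory": ["V1", "A3a", "A3b", "AuA1", "AuR", "Gu"],
  "koniocortex": ["V1", "A3b", "AuA1", "AuR"]
}
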