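{
  "n": 15,
  "positives": 6,
  "males": 5,
  "females": 10,
  "age_mean": 54,
  "age_sd": 11
}
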