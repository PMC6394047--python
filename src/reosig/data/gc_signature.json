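{
  "version": 1,
  "pairs": [
    {"gene_high": "CYR61", "gene_low": "MMP28"},
    {"gene_high": "CYR61", "gene_low": "ACOX1"}
  ],
  "vote_rule": "at_least_half"
}
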