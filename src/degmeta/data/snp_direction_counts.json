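{
  "genome_wide_tbp_norm": {
    "n_gene": 10000,
    "n_snp": 100000,
    "n_res": 1000,
    "n_gt": 200,
    "n_lt": 800,
    "n_to_ht": null,
    "n_from_ht": null
  },
  "candidate_markers": {
    "n_gene": 3,
    "n_snp": 85,
    "n_res": 27,
    "n_gt": 8,
    "n_lt": 19,
    "n_to_ht": 8,
    "n_from_ht": 19
  }
}
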