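# Small end-to-end demonstration run (seconds on one CPU).
seed: 7
cv_folds: 5
n_permutations: 100
simulate:
  n_lines: 80
  n_genes: 250
  n_drugs: 20
  n_candidates: 3
  n_tumors: 100
gsea:
  enabled: true
  n_permutations: 100
  n_decoy_sets: 8
  decoy_set_size: 20
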