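# Demo pipeline configuration: a small but complete run.
seed: 42

reference:
  n_mirna: 10
  n_pirna: 60
  n_sirna26g_ergo1: 4
  n_sirna26g_alg34: 4
  n_coding: 6
  n_motif_copies: 7

library:
  n_species: 50
  copy_mean: 20.0
  classes:
    siRNA_26G_ERGO1:
      tail_rate: 0.15

beta_elimination:
  p_meth: 1.0
  p_unmeth: 0.1

scan:
  min_complementarity: 0.69
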