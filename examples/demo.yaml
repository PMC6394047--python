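# Desk-scale end-to-end demo: a zero-noise cohort with two planted reversal
# pairs among 200 genes, three simulated platforms, and one GC specimen in a
# hundred at 14% tumor purity.  The low-purity specimen defeats the top
# single pair but not the two-pair majority vote, so
#   reosig all --config examples/demo.yaml --outdir out
# recovers both planted pairs (k* = 2) with training accuracy 1.0.
simulate:
  n_genes: 200
  class_sizes: {NORMAL: 50, GASTRITIS: 50, GC: 100, GC_ADJ: 10, IM: 10}
  noise_sd: 0.0
  n_batches: 3
  seed: 7
  # one of the hundred GC specimens is a 14%-purity mixture; with a hundred
  # GC samples the 99% stability rule tolerates exactly that one reversal
  purity_values: {0.14: 1, 1.0: 99}
  planted_pairs:
    - {gene_high: PAIR1HI, gene_low: PAIR1LO, delta_non: 2.2, delta_gc: 1.1, base_log2: 6.0}
    - {gene_high: PAIR2HI, gene_low: PAIR2LO, delta_non: 1.2, delta_gc: 3.4, base_log2: 12.0}
select:
  threshold: "0.99"
  vote_rule: at_least_half
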