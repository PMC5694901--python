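# Desk-scale synthetic study for the end-to-end pipeline (`starrkit all`).
# 10-Mb genome, 60 planted enhancers, ~100k raw reads per library.
seed: 7
simulate:
  n_enhancers: 60
  n_input_fragments: 90000
  n_output_fragments: 90000
  n_genes: 150
  n_signal_reads: 90000
  n_chromatin_input_reads: 90000
caller:
  window_size: 500
  step: 100
  merge_gap: 200
  min_peak_length: 200
  q_threshold: 0.05
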