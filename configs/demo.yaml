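# Demo pipeline configuration: simulates a small genus-structured catalog
# (sequences included) and runs every stage. Single CPU, a couple minutes.
outdir: runs/demo
seed: 1
simulate:
  n_phyla: 2
  orders_per_phylum: 1
  families_per_order: 1
  genera_per_family: 3
  genomes_per_genus: 8
  with_sequences: true
  prophage_seq_bp: 8000
  host_window_bp: 15000
  enriched_genera:
    2: 4.0
min_genomes: 5
bootstrap_min_genus: 8
bootstrap_n_genomes: 5
bootstrap_n_iter: 20
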