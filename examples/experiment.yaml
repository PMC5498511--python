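# A reduced experiment grid that runs in a few minutes on one CPU.
# Scale n_loci / qtl_counts / mcmc up for the full-size study.
generator:
  n_individuals: 200
  n_loci: 1000
  switch_rate: 0.05      # ~50 founder-mosaic blocks across the genome
  seed: 1

mcmc:
  n_iter: 1000
  burn_in: 250
  thin: 5

scenario:
  qtl_counts: [50, 100]
  heritabilities: [0.5, 0.2]
  panels: [mp1, mp2, mp3, mp4, mp5, mp6, mp7]
  models: [bayesB]
  n_replicates: 2
  train_size: 100
  master_seed: 9
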