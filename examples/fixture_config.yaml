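# Desk-scale fixture for the end-to-end pipeline: the full analysis chain on
# a small synthetic study (3 planted modules, 4 genetic groups x 5 stages x 6
# replicates, 80 hens/group). Module-size thresholds are scaled to the
# fixture; every statistical parameter keeps its standard default.
seed: 7
stages: [simulate, prep, heterosis, network, consensus, preservation,
         classify, enrichment]
simulate:
  n_genes: 240
  module_sizes: [50, 50, 50]
  module_cor: 0.6
  n_hens_per_group: 80
  windows: 10
  samples_per_cell: 6
  stages: 5
prep:
  fpkm_min: 0.1
  frac_samples: 0.30
  top_mad: 0.8
heterosis:
  crosses: [WY, YW]
  trait: egg_number
network:
  groups: [WW, YY, WY]
  power: 12
  min_module_size: 20
consensus:
  groups: [WW, YY, WY]
  power: 12
  min_module_size: 20
  kme_min: 0.70
  p_max: 1.0e-5
preservation:
  reference: WW
  tests: [YY, WY]
  n_perm: 50
classify:
  crosses: [WY]
  fdr: 0.05
enrichment: {}
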