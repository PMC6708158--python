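# Demo pipeline: six-cohort world, both clock methods, C2 held out for
# the mortality and enrichment experiments.
seed: 7
simulate:
  n_probes: 2000
  n_causal: 200
  target_rho2: 0.9
varcomp:
  enabled: true
  n_perm: 0
train:
  methods: [enet, blup]
  n_replicates: 2
  holdout: C2
survival:
  enabled: true
  covariates: [age, sex]
ewas:
  enabled: true
figures: true
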