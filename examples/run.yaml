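# Small end-to-end pipeline run: simulate -> qc -> traits -> fit -> cv.
outdir: runs/example
seed: 1
attrition_rate: 0.14
stages: [simulate, qc, traits, fit, cv]
simulation:
  n_families: 12
  fish_per_aquarium: 15
  n_batches: 4
  n_snps: 1500
  n_chromosomes: 10
traits: [FCR, BWG]
models: [PBLUP, GBLUP, ssGBLUP]
cv_mode: random_animal
cv_replicates: 5
cv_folds: 5
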