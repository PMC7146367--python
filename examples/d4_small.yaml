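# Small contraction-intensity study: D4-like shape, 3 MVC levels.
generator:
  preset: d4_like
  n_subjects: 2
  conditions: [0.2, 0.5, 0.8]
  reps_per_condition: 4
  trial_duration: 0.5
  seed: 11
features:
  sets: [TD]
evaluate:
  classifiers:
    - {name: lda}
  frameworks: [intra, single_vs_all, inter]
  seed: 11
output: scratch/d4_small
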