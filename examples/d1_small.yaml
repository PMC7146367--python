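# Small limb-position study: D1-like shape with 2 subjects and short trials.
generator:
  preset: d1_like
  n_subjects: 2
  reps_per_condition: 4
  trial_duration: 0.5
  seed: 7
preprocess:
  notch_freq: 50.0
  band: [20, 450]
  target_fs: 1000
  window_ms: 150
  increment_ms: 50
features:
  sets: [TD]
evaluate:
  classifiers:
    - {name: lda}
  frameworks: [intra, single_vs_all, inter]
  seed: 7
output: scratch/d1_small
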