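# Planted star-vs-chain demonstration study (see docs/methods.md).
seed: 7
bands:
  beta: [13, 30]
  gamma: [31, 46]
windows: {count: 5, ms: 100}
synth:
  n_subjects: 1
  trials_per_condition_per_subject: 150
  n_channels: 16
  coupling_strength: 0.9
  noise_sd: 1.0
  coupling:
    - {condition: face, band: beta, window: 2, topology: star, hub: 0}
    - {condition: face, band: gamma, window: 2, topology: star, hub: 0}
    - {condition: ketch, band: beta, window: 2, topology: chain}
    - {condition: ketch, band: gamma, window: 2, topology: chain}
split: {fraction: 0.7, seed: 11}
reference_condition: scrambled
contrast_conditions: [face, ketch]
alpha: 0.05
distance: reciprocal
svm: {folds: 5, repeats: 5, C: 1.0, gamma: scale}
stages: {classify: true, timesegment: false}
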