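# Demo "non-responder": same task and background activity, no task effects.
# The seed is fixed so the bundled demo shows no significant findings.
seed: 11
simulate:
  n_blocks: 3
  sampling_rate: 256.0
  artifact_rate: 0.0
  effects: []
preprocess:
  match_counts:
    left: 36
    right: 36
    rest: 34
spectral:
  n_perm: 1000
classify:
  n_perm: 1000
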