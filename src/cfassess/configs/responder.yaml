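# Demo "responder": synthetic patient who attempts left-hand movements,
# producing an ipsilateral high-beta ERS about 1 s after instruction offset.
seed: 7
simulate:
  n_blocks: 3
  sampling_rate: 256.0
  artifact_rate: 0.0
  effects:
    - condition: left
      band: [25.0, 30.0]
      depth: 1.0
      channel_side: ipsilateral
      latency: 1.0
      duration: 1.0
      ramp: 0.25
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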