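# cfassess

Bedside EEG assessment of covert command-following from sensorimotor
rhythms. The package implements, end to end:

- **Synthetic EEG** (`cfassess.synthetic`): the instruction task (blocks of
  36 trials, 12 per instruction — left hand / right hand / rest — with at
  most three consecutive repeats; 2 s instructions followed by 4–7 s of
  silence) and a 9-channel 256 Hz recording built from 1/f background,
  band-limited mu/beta oscillators, event-locked multiplicative ERD/ERS
  effects with configurable band/latency/duration/laterality/depth, and
  annotated broadband muscle artifacts.
- **Preprocessing** (`cfassess.preprocess`): anti-aliased resampling to
  100 Hz, zero-phase least-squares FIR band-pass 1–40 Hz, 6 s epochs
  time-locked to instruction onset (time axis relative to instruction
  offset, −2…+4 s), automated artifact rejection with an audit report,
  bipolar derivations C3′ = FC3 − CP3 and C4′ = FC4 − CP4, and seeded
  per-condition trial-count matching.
- **Average spectral statistics** (`cfassess.spectral`): fixed-window (1 s
  Hanning, 50 ms steps, end-labelled, 100 cells/epoch) time-frequency
  transform, log power-ratio contrasts, cluster-based permutation testing
  (per-cell t-tests at p < .05 two-tailed, 4-adjacency clustering by sign,
  cluster-sum statistic, max-cluster null over 1000 re-partitions, cluster
  threshold .0125 two-tailed) and pwelch-style whole-epoch spectra in dB.
- **Single-trial classification** (`cfassess.singletrial`): log bandpower
  in mu (7–13), low-beta (13–19), mid-beta (19–25) and high-beta (25–30 Hz)
  on both bipolar channels (8 features × 100 time-points), Gaussian naive
  Bayes with stratified 10-fold cross-validation, 500 ms smoothing, and a
  familywise max-statistic randomization test (1000 label shuffles,
  α = .025 one-tailed), plus band-restricted variants.
- **Orchestration** (`cfassess.report`, `cfassess.cli`): one YAML config
  drives the whole chain and produces JSON stage outputs, a Markdown
  report, and figures.

I/O: EDF (16-bit, self-contained reader/writer), BrainVision
(.vhdr/.eeg/.vmrk reader), a plain CSV fixture dialect, and TSV event
sidecars (`onset_sample<TAB>condition`).

## CLI

```sh
# full assessment from a config (simulate -> preprocess -> stats -> report)
cfassess assess -c src/cfassess/configs/responder.yaml -o out/

# individual stages
cfassess simulate  -c cfg.yaml -o out/ --format edf
cfassess preprocess -c cfg.yaml -i out/recording.edf -o out/
cfassess classify  -c cfg.yaml -o out/ --left --bands high-beta --n-perm 1000 --seed 7
cfassess report    -r out/           # regenerate report.md from report.json
```

Bundled demo configs: `configs/responder.yaml` (synthetic patient with an
ipsilateral high-beta ERS on left-hand trials — yields a significant
cluster and significant classification time-points) and `configs/null.yaml`
(no task effects — no findings). Exit codes: 0 success, 2 config error,
3 data error; significance is a finding, not an exit status.

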