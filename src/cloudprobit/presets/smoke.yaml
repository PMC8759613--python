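# Tiny end-to-end preset: completes in well under two minutes.
seed: 0
generator:
  n_participants: 20
  n_stations: 3
  study_days: 60
  entry_window: 20
  followup_median: 30.0
  followup_iqr: [20.0, 45.0]
sampler:
  n_chains: 2
  n_warmup: 150
  n_keep: 150
report:
  n_ppc: 50
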