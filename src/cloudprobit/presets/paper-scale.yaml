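# Qualitative preset with the published population coefficient magnitudes.
# Effects this small are not recoverable at desk scale; use for format and
# shape checks, not recovery tests.
seed: 0
generator:
  n_participants: 1000
  gamma: [-0.003, -0.010, 0.041, 0.012]
  random_effect_sd: [0.5, 0.01, 0.02, 0.04, 0.01]
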