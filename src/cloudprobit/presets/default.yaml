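# Desk-scale study: 300 participants, decisive latent effect sizes,
# cohort descriptors calibrated to the published study population.
seed: 0
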