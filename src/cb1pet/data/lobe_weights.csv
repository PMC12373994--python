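region,weight
frontal,0.30
temporal,0.23
parietal,0.16
occipital,0.13
cerebellum,0.18
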