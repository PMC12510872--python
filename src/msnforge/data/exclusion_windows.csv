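center_mz,width
149.72,0.03
173.52,0.03
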