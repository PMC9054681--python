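n_AA	n_AG	n_GG	n_A	n_G
229	24	1	312	14
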