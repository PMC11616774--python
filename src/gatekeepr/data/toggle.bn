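# two-node wire: each node copies the other
targets, factors
A, B
B, A
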