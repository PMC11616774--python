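# two parallel shortest paths a->b->d and a->c->d
targets, factors
a, a
b, a
c, a
d, b | c
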