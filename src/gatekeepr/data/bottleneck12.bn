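# two dense clusters (c1-c5, d1-d6) joined only via the low-degree bridge b;
# all cross-cluster shortest paths run c5 -> b -> d1
targets, factors
c1, c2 & c3
c2, c1 | c3
c3, c1 & c2
c4, c1 | c2
c5, c3 & c4
b, c5
d1, b
d2, d1 & d3
d3, d2 | d4
d4, d3 & d5
d5, d1 | d2
d6, d4 | d5
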