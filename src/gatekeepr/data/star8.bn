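# constant source feeding 8 leaves; the center is a degree hub
targets, factors
hub, 0
l1, hub
l2, hub
l3, hub
l4, hub
l5, hub
l6, hub
l7, hub
l8, hub
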