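# single self-inhibiting node, period-2 oscillator
targets, factors
A, !A
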