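# Multi-word "empty speech" patterns beyond single fillers, matched over
# normalized tokens.
yeah i guess
uh huh
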