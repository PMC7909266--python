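# Filler ("empty speech") word list, one entry per line; multi-word entries
# are matched as token bigrams. Editable; this is the packaged default.
um
uh
er
hm
mhm
you know
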