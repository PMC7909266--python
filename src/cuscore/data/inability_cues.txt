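# Cue phrases for statements about inability to decipher the picture or
# retrieve a word. Matched over normalized tokens, longest phrase first.
i'm not quite sure
i'm not sure
not sure
can't think of that
can't think
can't remember
don't know
hard to say
what's it called
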