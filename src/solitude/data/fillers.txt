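# Filled-pause / dysfluency lexicon, one entry per line; multiword allowed.
um
uh
er
ah
hmm
mhm
uh-huh
you know
i mean
sort of
kind of
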