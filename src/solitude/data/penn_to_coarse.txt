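# Penn-Treebank tag -> coarse tag mapping for external tagger adapters.
NN	noun
NNS	noun
NNP	noun
NNPS	noun
VB	verb
VBD	verb
VBG	verb
VBN	verb
VBP	verb
VBZ	verb
MD	verb
JJ	adjective
JJR	adjective
JJS	adjective
RB	adverb
RBR	adverb
RBS	adverb
WRB	adverb
PRP	pronoun
PRP$	pronoun
WP	pronoun
WP$	pronoun
UH	interjection
DT	other
IN	other
CC	other
TO	other
CD	other
EX	other
PDT	other
POS	other
RP	other
FW	other
LS	other
SYM	other
WDT	other
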