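# Packaged valence lexicon (token <TAB> valence), additive scorer range ~[-4, 4].
# A compact general-purpose list oriented to conversational interview speech.
love	3.2
loved	2.9
loving	2.9
enjoy	2.3
enjoyed	2.3
wonderful	2.7
happy	2.6
happiness	2.7
great	3.1
good	1.9
best	3.2
nice	1.8
meaningful	1.7
caring	2.2
cared	1.9
blessed	2.9
fun	2.3
laugh	2.6
laughing	2.6
support	1.7
supportive	2.0
comfort	1.9
comforting	2.0
grateful	2.4
thankful	2.3
joy	2.8
kind	2.4
warm	1.6
proud	2.1
cherish	2.3
close	1.1
dear	1.8
special	1.7
glad	2.0
pleasant	1.9
friendly	2.2
helpful	1.9
lucky	1.9
beautiful	2.9
sweet	2.0
lonely	-2.5
loneliness	-2.5
alone	-1.0
sad	-2.1
sadness	-2.1
difficult	-1.5
worried	-2.3
worry	-2.0
miss	-1.4
missed	-1.4
lost	-1.3
tired	-1.7
empty	-1.8
isolated	-2.2
isolation	-2.1
struggle	-2.0
struggling	-2.0
pain	-2.3
painful	-2.4
afraid	-2.2
upset	-2.1
stress	-2.0
stressful	-2.1
disconnected	-1.7
depressed	-2.7
anxious	-2.0
hurt	-2.2
hurts	-2.2
terrible	-3.0
awful	-2.9
bad	-2.5
frustrating	-2.1
frustrated	-2.1
grief	-2.5
cry	-2.0
sick	-1.8
forgotten	-1.6
burden	-1.9
hard	-0.8
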