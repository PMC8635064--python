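# Word -> coarse POS tag for the packaged dictionary tagger (tab-separated).
# Coarse tag set: noun verb adjective adverb pronoun interjection filler other
i	pronoun
me	pronoun
my	pronoun
mine	pronoun
myself	pronoun
we	pronoun
our	pronoun
us	pronoun
ours	pronoun
ourselves	pronoun
he	pronoun
she	pronoun
they	pronoun
them	pronoun
their	pronoun
theirs	pronoun
themselves	pronoun
him	pronoun
her	pronoun
hers	pronoun
himself	pronoun
herself	pronoun
you	pronoun
your	pronoun
yours	pronoun
yourself	pronoun
it	pronoun
its	pronoun
itself	pronoun
everyone	pronoun
someone	pronoun
anyone	pronoun
nobody	pronoun
somebody	pronoun
am	verb
is	verb
are	verb
was	verb
were	verb
be	verb
been	verb
being	verb
have	verb
has	verb
had	verb
do	verb
does	verb
did	verb
can	verb
could	verb
will	verb
would	verb
should	verb
may	verb
might	verb
must	verb
go	verb
goes	verb
went	verb
get	verb
gets	verb
got	verb
see	verb
sees	verb
saw	verb
know	verb
knows	verb
knew	verb
think	verb
thinks	verb
thought	verb
feel	verb
feels	verb
felt	verb
talk	verb
talks	verb
spend	verb
spends	verb
spent	verb
live	verb
lives	verb
visit	verb
visits	verb
like	verb
try	verb
tries	verb
keep	verb
keeps	verb
make	verb
makes	verb
made	verb
say	verb
says	verb
said	verb
come	verb
comes	verb
came	verb
take	verb
takes	verb
took	verb
help	verb
helps	verb
stay	verb
stays	verb
meet	verb
meets	verb
met	verb
understand	verb
understands	verb
understood	verb
care	verb
cares	verb
connect	verb
connects	verb
stop	verb
stopped	verb
seem	verb
seems	verb
good	adjective
great	adjective
happy	adjective
wonderful	adjective
nice	adjective
close	adjective
important	adjective
meaningful	adjective
lonely	adjective
sad	adjective
difficult	adjective
hard	adjective
busy	adjective
tired	adjective
empty	adjective
isolated	adjective
afraid	adjective
upset	adjective
terrible	adjective
awful	adjective
bad	adjective
proud	adjective
grateful	adjective
warm	adjective
kind	adjective
best	adjective
old	adjective
young	adjective
large	adjective
small	adjective
long	adjective
quiet	adjective
whole	adjective
dear	adjective
special	adjective
glad	adjective
supportive	adjective
very	adverb
really	adverb
often	adverb
always	adverb
never	adverb
usually	adverb
sometimes	adverb
together	adverb
nearby	adverb
here	adverb
there	adverb
now	adverb
then	adverb
too	adverb
also	adverb
still	adverb
just	adverb
hardly	adverb
mostly	adverb
rarely	adverb
anymore	adverb
fully	adverb
oh	interjection
wow	interjection
yeah	interjection
yes	interjection
no	interjection
gosh	interjection
goodness	interjection
um	filler
uh	filler
er	filler
ah	filler
hmm	filler
mhm	filler
uh-huh	filler
the	other
a	other
an	other
of	other
in	other
on	other
at	other
to	other
for	other
with	other
and	other
but	other
or	other
so	other
if	other
because	other
as	other
by	other
from	other
about	other
into	other
over	other
after	other
before	other
when	other
while	other
than	other
that	other
which	other
who	other
whom	other
what	other
these	other
those	other
this	other
not	other
up	other
out	other
down	other
how	other
each	other
every	other
all	other
some	other
any	other
most	other
few	other
more	other
much	other
one	other
two	other
three	other
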