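# contraction/shortcut <TAB> expansion; keys are matched as whole words on
# lowercased text before punctuation stripping.
i'm	i am
i've	i have
i'll	i will
i'd	i would
you're	you are
you've	you have
you'll	you will
you'd	you would
he's	he is
he'll	he will
he'd	he would
she's	she is
she'll	she will
she'd	she would
it's	it is
it'll	it will
we're	we are
we've	we have
we'll	we will
we'd	we would
they're	they are
they've	they have
they'll	they will
they'd	they would
isn't	is not
aren't	are not
wasn't	was not
weren't	were not
hasn't	has not
haven't	have not
hadn't	had not
doesn't	does not
don't	do not
didn't	did not
won't	will not
wouldn't	would not
can't	can not
couldn't	could not
shouldn't	should not
mightn't	might not
mustn't	must not
needn't	need not
shan't	shall not
let's	let us
that's	that is
who's	who is
what's	what is
here's	here is
there's	there is
where's	where is
when's	when is
why's	why is
how's	how is
y'all	you all
ain't	am not
im	i am
ive	i have
dont	do not
cant	can not
wont	will not
thx	thanks
ty	thanks
u	you
ur	your
r	are
pls	please
plz	please
idk	i do not know
imo	in my opinion
imho	in my opinion
btw	by the way
lol	laughing
lmao	laughing
rofl	laughing
omg	oh my god
tbh	to be honest
rn	right now
irl	in real life
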