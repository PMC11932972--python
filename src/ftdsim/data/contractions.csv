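contraction,expansion
aren't,are not
can't,cannot
couldn't,could not
didn't,did not
doesn't,does not
don't,do not
hadn't,had not
hasn't,has not
haven't,have not
he'd,he would
he'll,he will
he's,he is
i'd,i would
i'll,i will
i'm,i am
i've,i have
isn't,is not
it'd,it would
it'll,it will
it's,it is
let's,let us
mightn't,might not
mustn't,must not
shan't,shall not
she'd,she would
she'll,she will
she's,she is
shouldn't,should not
that's,that is
there's,there is
they'd,they would
they'll,they will
they're,they are
they've,they have
wasn't,was not
we'd,we would
we'll,we will
we're,we are
we've,we have
weren't,were not
what's,what is
where's,where is
who's,who is
won't,will not
wouldn't,would not
you'd,you would
you'll,you will
you're,you are
you've,you have
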