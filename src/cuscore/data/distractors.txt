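# Distractor vocabulary for the synthetic-transcript generator: task-irrelevant
# function/filler-adjacent words guaranteed not to match any lexicon variant
# (or inflection thereof), filler, inability cue, or empty-speech phrase.
# Screened programmatically at load time; a collision is a build error.
the
a
an
and
then
it
its
is
are
was
were
be
been
they
them
their
he
she
we
his
her
our
this
that
these
those
there
here
some
any
all
just
very
so
but
or
if
when
while
now
also
well
of
to
for
from
into
out
up
down
off
about
because
maybe
perhaps
seems
looks
like
doing
going
one
other
another
each
something
things
stuff
not
really
rather
lot
bit
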