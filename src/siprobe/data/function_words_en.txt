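# English function words: articles, prepositions, auxiliary verbs, and the
# conjunction "and". One token per line; lines starting with '#' are ignored.
# Users may supply their own list via the `word_list` argument of
# siprobe.lexical.classify_word.
# articles
a
an
the
# conjunction
and
# prepositions
aboard
about
above
across
after
against
along
amid
among
around
as
at
before
behind
below
beneath
beside
besides
between
beyond
by
despite
down
during
except
for
from
in
inside
into
near
of
off
on
onto
out
outside
over
past
per
since
through
throughout
till
to
toward
towards
under
underneath
until
unto
up
upon
versus
via
with
within
without
# auxiliary verbs
am
are
be
been
being
can
could
did
do
does
had
has
have
having
is
may
might
must
ought
shall
should
was
were
will
would
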