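# English stop words: pronouns, contractions (apostrophe-free, as they appear
# after punctuation removal), articles, auxiliaries and prepositions.
# Words listed in retain.txt are exempted at load time.
a
about
above
after
again
against
all
am
an
and
any
are
arent
as
at
be
because
been
before
being
below
between
both
but
by
cannot
cant
could
couldnt
did
didnt
do
does
doesnt
doing
dont
down
during
each
few
for
from
further
had
hadnt
has
hasnt
have
havent
having
he
hed
hell
her
here
heres
hers
herself
hes
him
himself
his
how
hows
i
id
if
ill
im
in
into
is
isnt
it
its
itself
ive
lets
me
more
most
mustnt
my
myself
no
nor
not
of
off
on
once
only
or
other
ought
our
ours
ourselves
out
over
own
per
same
shant
she
shed
shell
shes
should
shouldnt
so
some
such
than
that
thats
the
their
theirs
them
themselves
then
there
theres
these
they
theyd
theyll
theyre
theyve
this
those
through
to
too
under
until
up
very
was
wasnt
we
wed
well
were
werent
weve
what
whats
when
whens
where
wheres
which
while
who
whom
whos
why
whys
will
with
wont
would
wouldnt
you
youd
youll
your
youre
yours
yourself
yourselves
youve
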