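a
an
and
are
as
at
be
been
by
for
from
has
have
in
into
is
it
its
of
on
or
over
such
that
the
their
these
this
to
under
upon
was
were
which
whose
will
with
within
without
we
our
using
used
study
studies
analysis
data
sample
samples
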