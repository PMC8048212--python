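# Implicit temporal signals: cue words and phrases marking temporal relations.
# One entry per line; '#' starts a comment; matching is case-insensitive and
# longest-match-wins.  Edit freely or point find_temporal_expressions at a
# custom lexicon.
before
after
prior to
following
then
subsequently
since
until
during
while
once
afterwards
meanwhile
as soon as
at the time of
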