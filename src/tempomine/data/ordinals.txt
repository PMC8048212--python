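# Ordinal words marking position in a sequence of clinical events.
first
second
third
fourth
fifth
sixth
seventh
eighth
ninth
tenth
initially
finally
lastly
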