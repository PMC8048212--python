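"""Align notes on the external timeline and detect temporal expressions.

The external timeline expresses each note's timestamp as a signed offset in
hours from an anchor event (death or discharge), so notes of many patients
can be pooled at comparable offsets.  The internal timeline is recovered
from the text itself via three categories of temporal expression.
"""

from tempomine import (
    GeneratorConfig,
    align_external,
    duration_between,
    find_temporal_expressions,
    generate,
)

corpus, _ = generate(GeneratorConfig(n_patients=3, seed=3))
aligned = align_external(corpus, anchor="discharge")
print("external timeline (offsets are hours before discharge):")
for a in aligned[:6]:
    print(f"  {a.note.patient_id} {a.note.note_id} offset {a.offset_hours:+.1f} h")

text = "First fever for 2 days, then hypotension since DD-MM-YYYY 10:02."
print(f"\ninternal timeline of: {text!r}")
for e in find_temporal_expressions(text):
    print(f"  [{e.start:>2}:{e.end:<2}] {e.category:<15} {e.surface!r} -> {e.normalized}")

# The masked de-identification dialect: 'DD-MM-YYYY' is an unknown but
# fixed reference date, '+ n' means n calendar days later.  Durations
# between masked instants are still well defined:
exprs = find_temporal_expressions("from DD-MM-YYYY 10:02 to + 2 DD-MM-YYYY 04:26")
hours, days = duration_between(exprs[0].normalized, exprs[1].normalized)
print(f"\nmasked interval spans {hours} h (floor) or {days} days (calendar difference)")
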