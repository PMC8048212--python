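"""Generate a synthetic sepsis-note corpus and inspect its ground truth.

Real sepsis note corpora are access-restricted, so the toolkit ships a
seeded generator that plants duplicates, timelines, temporal expressions
and ordered symptom patterns — and records exactly what it planted.
"""

from tempomine import GeneratorConfig, generate

config = GeneratorConfig(n_patients=5, seed=42)
corpus, truth = generate(config)

print(f"corpus: {len(corpus)} note records for {len(corpus.patients())} patients")
print(f"duplicated notes (same note_id, higher line_nbr): {len(truth.duplicates)}")
print(f"planted ordered symptom patterns: {len(truth.pattern_instances)} instances")

note = corpus.notes[0]
print(f"\nfirst note ({note.note_id}, {note.note_type}, {note.timestamp}):")
print(note.text)
# The printed note mixes boilerplate with symptom sentences; each symptom
# sentence carries exactly one planted temporal expression whose surface,
# category and normalized value are recorded in truth.temporal.
print("\nplanted expressions in this note:", truth.temporal[(note.note_id, note.line_nbr)])
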