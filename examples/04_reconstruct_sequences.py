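"""Reconstruct free text into a time-stamped clinical-entity sequence database.

Sentences with temporal intent are decomposed into a non-temporal
sub-expression plus temporal constraints; sub-expressions are clustered
into entity labels with K-medoids (every label exemplified by a real
sub-expression); entities then form per-patient (time, itemset) sequences.
"""

from tempomine import (
    GeneratorConfig,
    build_sequences,
    decompose,
    deduplicate,
    find_temporal_expressions,
    generate,
    reconstruct_corpus,
)

sentence = "fever for 2 days"
d = decompose(sentence, find_temporal_expressions(sentence))
print(f"{sentence!r} -> sub-expression {d.sub_expression!r}, constraints {d.constraints}")

config = GeneratorConfig(n_patients=10, seed=5)
corpus, _ = generate(config)
entities, model = reconstruct_corpus(
    deduplicate(corpus), k_entities=len(config.symptom_vocabulary), seed=1
)
print(f"\n{len(entities)} timed entities under {len(model.medoids)} entity labels")
print("entity labels (medoid exemplars):", sorted(model.medoids.values()))

db = build_sequences(entities, mode="timed")
pid = next(iter(db.sequences))
print(f"\nsequence for patient {pid} (time index -> itemset):")
for t, items in db.sequences[pid]:
    print(f"  t{t}: {list(items)}")
# The same relation can be viewed per-time instead of per-patient:
print("\nper-time view (first rows):")
print(db.to_frame("time").head(5).to_string(index=False))
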