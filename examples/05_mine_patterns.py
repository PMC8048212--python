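"""Mine ordered frequent symptom patterns with PrefixSpan.

Support counts patients (once per sequence); the report mirrors the
Freq/Pattern table format used for sepsis symptom patterns.
"""

from tempomine import (
    GeneratorConfig,
    build_sequences,
    deduplicate,
    filter_patterns,
    format_report,
    generate,
    prefixspan,
    reconstruct_corpus,
    top_k_report,
)

config = GeneratorConfig(n_patients=40, seed=11)
corpus, _ = generate(config)
entities, _ = reconstruct_corpus(
    deduplicate(corpus), k_entities=len(config.symptom_vocabulary), seed=1
)
db = build_sequences(entities, mode="timed")

patterns = prefixspan(db, min_support=10)
multi = filter_patterns(patterns, min_length=2)  # drop singleton patterns
print(f"{len(patterns)} patterns at min_support=10 over {len(db.sequences)} patients,")
print(f"{len(multi)} of them multi-item.  Top 10:\n")
print(format_report(top_k_report(multi, k=10)))
# Freq is the number of patients whose symptom sequence contains the
# pattern in order; the generator plants three ordered pairs at
# probability 0.9, and those dominate the top of the table.
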