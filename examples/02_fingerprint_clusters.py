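"""Embed notes into SimHash fingerprints, cluster them, pick exemplars.

Fingerprints place similar documents at small Hamming distance; K-means
over the bit vectors groups note sublanguages, and each cluster is
summarised by a *representative* — the real note closest to the centroid,
meant to be read by a human.
"""

from tempomine import GeneratorConfig, cluster_fingerprints, fingerprint_corpus, generate

corpus, _ = generate(GeneratorConfig(n_patients=15, seed=7))
fps = fingerprint_corpus(corpus, bits=64, weighting="tfidf", hash_seed=1)
model = cluster_fingerprints(fps, k=5, seed=1)

print(f"{len(fps)} fingerprints of width 64, K=5 clusters")
print(f"objective (within-cluster squared distance): {model.objective:.1f}")
print(f"objective per iteration (never increases): "
      f"{[round(o, 1) for o in model.objective_history]}")

by_note = {n.note_id: n for n in corpus.notes}
for cluster, rep in sorted(model.representatives.items()):
    size = sum(1 for c in model.assignments.values() if c == cluster)
    first_line = by_note[rep.split('#')[0]].text.splitlines()[0]
    print(f"cluster {cluster} ({size:>3} notes) exemplar {rep}: {first_line!r}")
# Each exemplar is an actual input note — reading K exemplars conveys the
# spread of note types in the corpus without reading every note.
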