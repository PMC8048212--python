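"""SimHash fingerprints, Hamming distance and K-means clustering."""

import math
import random
import time

import numpy as np
import pytest

from tempomine import (
    Corpus,
    ClinicalNote,
    Fingerprint,
    cluster_fingerprints,
    document_frequencies,
    fingerprint_corpus,
    hamming,
    representatives,
    simhash,
    split_sections,
    tokenize,
)
from tempomine.errors import ParameterError

from helpers_oracles import planted_fingerprint_groups


# ---------------------------------------------------------------------------
# tokenisation


def test_tf_weighting_counts_terms():
    assert tokenize("Fever fever chills") == {"fever": 2, "chills": 1}


def test_empty_text_gives_empty_bag():
    assert tokenize("") == {}


def test_idf_zero_for_token_in_every_document():
    texts = ["fever chills", "fever cough"]
    df, n = document_frequencies(texts)
    bag = tokenize("fever chills", df, n)
    assert bag["fever"] == 0.0
    assert bag["chills"] == pytest.approx(math.log(2))


# ---------------------------------------------------------------------------
# simhash


def test_identical_bags_identical_fingerprints():
    bag = tokenize("patient febrile overnight with rigors")
    a, b = simhash(bag, 64, hash_seed=3), simhash(bag, 64, hash_seed=3)
    assert hamming(a, b) == 0


def test_single_token_fingerprint_is_its_hash():
    from tempomine.fingerprint import _token_bits

    fp = simhash({"x": 1.0}, 64, hash_seed=0)
    assert np.array_equal(fp.bits, _token_bits("x", 64, 0))


def test_empty_bag_gives_all_zero_fingerprint():
    assert simhash({}, 64).bits.sum() == 0


def test_unsupported_width_rejected():
    with pytest.raises(ParameterError):
        simhash({"a": 1.0}, 48)


@pytest.mark.parametrize("bits", [32, 64, 128])
def test_disjoint_vocabularies_give_near_half_width_distance(bits):
    """Monte-Carlo: unrelated documents land ~B/2 apart."""
    rng = random.Random(17)
    dists = []
    for i in range(200):
        left = {f"l{i}_{j}": 1.0 for j in range(10)}
        right = {f"r{i}_{j}": 1.0 for j in range(10)}
        dists.append(hamming(simhash(left, bits, 1), simhash(right, bits, 1)))
    mean = sum(dists) / len(dists)
    assert abs(mean - bits / 2) <= 0.10 * (bits / 2)


def test_locality_similar_documents_are_closer_than_unrelated():
    rng = random.Random(23)
    near, far = [], []
    for i in range(100):
        base = {f"t{i}_{j}": 1.0 for j in range(20)}
        variant = dict(base)
        # replace 2 of 20 tokens: 90% shared weighted tokens
        for j in range(2):
            del variant[f"t{i}_{j}"]
            variant[f"v{i}_{j}"] = 1.0
        other = {f"o{i}_{j}": 1.0 for j in range(20)}
        near.append(hamming(simhash(base, 64, 2), simhash(variant, 64, 2)))
        far.append(hamming(simhash(base, 64, 2), simhash(other, 64, 2)))
    assert sum(near) / len(near) < sum(far) / len(far)


def test_hex_round_trip():
    fp = simhash(tokenize("some note text"), 64, note_ref="n1")
    back = Fingerprint.from_hex(fp.to_hex(), 64, note_ref="n1")
    assert hamming(fp, back) == 0


# ---------------------------------------------------------------------------
# hamming


def test_hamming_identity_and_complement():
    fp = simhash(tokenize("alpha beta"), 64)
    assert hamming(fp, fp) == 0
    comp = Fingerprint(bits=1 - fp.bits)
    assert hamming(fp, comp) == 64


def test_hamming_matches_bitwise_loop_oracle():
    rng = random.Random(3)
    for _ in range(50):
        w = rng.choice([8, 12, 16])
        a = np.array([rng.randint(0, 1) for _ in range(w)], dtype=np.uint8)
        b = np.array([rng.randint(0, 1) for _ in range(w)], dtype=np.uint8)
        expected = sum(1 for x, y in zip(a, b) if x != y)
        assert hamming(Fingerprint(bits=a), Fingerprint(bits=b)) == expected


def test_hamming_width_mismatch_rejected():
    with pytest.raises(ParameterError):
        hamming(simhash({"a": 1.0}, 32), simhash({"a": 1.0}, 64))


# ---------------------------------------------------------------------------
# clustering


def _random_fps(n, rng, width=64):
    return [
        Fingerprint(
            bits=np.array([rng.randint(0, 1) for _ in range(width)], dtype=np.uint8),
            note_ref=f"n{i:03d}",
        )
        for i in range(n)
    ]


def test_k_equals_n_gives_zero_objective():
    fps = _random_fps(6, random.Random(1))
    model = cluster_fingerprints(fps, k=6, seed=0)
    assert model.objective == 0.0
    assert sorted(model.assignments.values()) == list(range(6))


def test_k_one_centroid_is_per_bit_mean():
    fps = _random_fps(9, random.Random(2))
    model = cluster_fingerprints(fps, k=1, seed=0)
    assert set(model.assignments.values()) == {0}
    X = np.stack([fp.bits for fp in fps]).astype(float)
    assert np.allclose(model.centroids[0], X.mean(axis=0))


def test_planted_two_group_partition_recovered():
    fps, labels = planted_fingerprint_groups(np.random.default_rng(4))
    model = cluster_fingerprints(fps, k=2, seed=0)
    got = [model.assignments[fp.note_ref] for fp in fps]
    split = {(l, g) for l, g in zip(labels, got)}
    assert len(split) == 2  # a perfect 1-1 relabelling of the planted groups


def test_objective_non_increasing_every_iteration():
    rng = random.Random(6)
    for seed in range(5):
        fps = _random_fps(40, rng)
        model = cluster_fingerprints(fps, k=4, seed=seed)
        hist = model.objective_history
        assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))


def test_invalid_k_rejected():
    fps = _random_fps(4, random.Random(0))
    with pytest.raises(ParameterError):
        cluster_fingerprints(fps, k=5)
    with pytest.raises(ParameterError):
        cluster_fingerprints(fps, k=0)


def test_deterministic_for_fixed_seed():
    fps = _random_fps(30, random.Random(8))
    a = cluster_fingerprints(fps, k=3, seed=42)
    b = cluster_fingerprints(fps, k=3, seed=42)
    assert a.assignments == b.assignments
    assert a.representatives == b.representatives


# ---------------------------------------------------------------------------
# representatives


def test_singleton_cluster_representative_is_its_member():
    fps, _ = planted_fingerprint_groups(np.random.default_rng(5), per_group=1)
    model = cluster_fingerprints(fps, k=2, seed=0)
    assert set(model.representatives.values()) == {fp.note_ref for fp in fps}


def test_representative_minimises_distance_exhaustively():
    rng = random.Random(11)
    fps = _random_fps(60, rng)
    model = cluster_fingerprints(fps, k=5, seed=1)
    by_ref = {fp.note_ref: fp for fp in fps}
    for cl, rep in model.representatives.items():
        rep_d = ((by_ref[rep].bits - model.centroids[cl]) ** 2).sum()
        for ref, assigned in model.assignments.items():
            if assigned == cl:
                assert rep_d <= ((by_ref[ref].bits - model.centroids[cl]) ** 2).sum() + 1e-9
        assert model.assignments[rep] == cl  # representative sits in its own cluster


def test_representatives_are_distinct_real_notes():
    fps = _random_fps(25, random.Random(14))
    model = cluster_fingerprints(fps, k=5, seed=3)
    reps = list(model.representatives.values())
    assert len(set(reps)) == len(reps)
    assert set(reps) <= {fp.note_ref for fp in fps}


# ---------------------------------------------------------------------------
# corpus-level embedding


def test_fingerprint_corpus_and_sections(small_synthetic):
    _, corpus, _ = small_synthetic
    fps = fingerprint_corpus(corpus, bits=64, weighting="tfidf", hash_seed=5)
    assert len(fps) == len(corpus)
    assert len({fp.note_ref for fp in fps}) == len(fps)
    sections = split_sections("Assessment: stable\n\nPlan: continue abx")
    assert set(sections) == {"assessment", "plan"}


def test_embedding_scales_linearly_smoke():
    """Coarse scalability smoke check: doubling n must not blow up runtime."""
    rng = random.Random(21)

    def run(n):
        corpus = Corpus(
            notes=[
                ClinicalNote(
                    f"N{i}",
                    1,
                    f"P{i}",
                    " ".join(rng.choice("abcdefgh") * 3 for _ in range(30)),
                )
                for i in range(n)
            ]
        )
        t0 = time.perf_counter()
        fingerprint_corpus(corpus, bits=64)
        return time.perf_counter() - t0

    run(50)  # warm-up
    t1 = min(run(300) for _ in range(3))
    t2 = min(run(600) for _ in range(3))
    assert t2 <= 3 * t1 or t2 < 0.05  # tiny absolute times are noise-dominated
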