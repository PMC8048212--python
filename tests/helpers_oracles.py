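"""Independent oracles used across the test suite.

These deliberately avoid the library's own algorithms: pattern containment
is a greedy leftmost scan, enumeration walks the raw candidate space, and
grouping is done with plain dictionaries, so agreement with the package is
meaningful evidence rather than a tautology.
"""

from __future__ import annotations

import random

import numpy as np


def contains_chain(seq: list[tuple], pattern: tuple) -> bool:
    """Greedy leftmost check that ``pattern`` is an ordered subsequence of
    ``seq`` (one item per strictly increasing itemset position)."""
    idx = 0
    for item in pattern:
        while idx < len(seq) and item not in seq[idx]:
            idx += 1
        if idx == len(seq):
            return False
        idx += 1
    return True


def bruteforce_patterns(seqs, min_support: int, max_length: int | None = None) -> dict:
    """Enumerate every frequent ordered single-item pattern by direct
    containment counting (candidate tree pruned only by the mathematical
    anti-monotonicity of subsequence support)."""
    alphabet = sorted({i for s in seqs for itemset in s for i in itemset}, key=str)
    cap = max_length if max_length is not None else max((len(s) for s in seqs), default=0)
    out: dict[tuple, int] = {}

    def grow(prefix: tuple):
        for a in alphabet:
            pat = prefix + (a,)
            sup = sum(contains_chain(s, pat) for s in seqs)
            if sup >= min_support:
                out[pat] = sup
                if len(pat) < cap:
                    grow(pat)

    grow(())
    return out


def random_database(rng: random.Random, max_seqs=6, n_items=5, max_len=6):
    """A random singleton-itemset sequence database for oracle comparison."""
    alphabet = [chr(ord("A") + i) for i in range(n_items)]
    n_seqs = rng.randint(1, max_seqs)
    return [
        [(rng.choice(alphabet),) for _ in range(rng.randint(1, max_len))] for _ in range(n_seqs)
    ]


def group_max_line(notes) -> dict:
    """Brute-force grouping oracle: (patient_id, note_id) -> max line_nbr."""
    best: dict[tuple[str, str], int] = {}
    for n in notes:
        key = (n.patient_id, n.note_id)
        best[key] = max(best.get(key, 0), n.line_nbr)
    return best


def planted_fingerprint_groups(rng: np.random.Generator, width=64, per_group=10, separation=32):
    """Two tight groups of bit vectors: within-group Hamming <= 2 (at most one
    flipped bit from the group base), between-group >= separation - 2."""
    from tempomine import Fingerprint

    base1 = rng.integers(0, 2, width).astype(np.uint8)
    base2 = base1.copy()
    flip = rng.choice(width, size=separation, replace=False)
    base2[flip] ^= 1
    fps, labels = [], []
    for g, base in enumerate((base1, base2)):
        for i in range(per_group):
            bits = base.copy()
            if i > 0:  # keep the base itself in each group
                bits[int(rng.integers(width))] ^= 1
            fps.append(Fingerprint(bits=bits, note_ref=f"g{g}n{i:02d}"))
            labels.append(g)
    return fps, labels
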