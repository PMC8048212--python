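"""SimHash document fingerprints and Hamming-space K-means clustering.

Each document is reduced to a weighted token bag and embedded into a
fixed-width binary fingerprint with Charikar's SimHash construction: every
token is hashed to B bits; a length-B accumulator adds ``+weight`` at
positions where the token's hash bit is 1 and ``-weight`` where it is 0; the
fingerprint bit is 1 where the accumulator is positive.  Similar documents
therefore receive fingerprints at small Hamming distance, and a corpus of n
notes embeds in a single O(n) pass.

Fingerprints are then partitioned with Lloyd-style K-means over the bit
vectors (centroids are per-bit means; assignment minimises Euclidean
distance, which on binary points coincides with Hamming distance to binary
centroids), and each cluster is summarised by a *representative*: the real
input note whose fingerprint lies closest to the centroid.  Representatives
are meant for human inspection — reading K exemplar notes gives a quick
sense of the sublanguages present in a corpus.
"""

from __future__ import annotations

import hashlib
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus import Corpus
from .errors import ParameterError

SUPPORTED_WIDTHS = (32, 64, 128)

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(
    text: str,
    document_frequency: Mapping[str, int] | None = None,
    n_documents: int | None = None,
) -> dict[str, float]:
    """Lowercase alphanumeric token bag with TF or TF-IDF weights.

    With only ``text`` given, weights are raw term frequencies.  When a
    corpus-level document-frequency table and the corpus size are supplied,
    weights become ``tf * ln(n_documents / df)``; a token present in every
    document then weighs exactly zero.  Tokens absent from the table are
    treated as df = 1.
    """
    counts = Counter(_TOKEN_RE.findall(text.lower()))
    if document_frequency is None:
        return dict(counts)
    if n_documents is None:
        raise ParameterError("n_documents is required when document_frequency is given")
    return {
        tok: tf * math.log(n_documents / max(1, document_frequency.get(tok, 1)))
        for tok, tf in counts.items()
    }


def document_frequencies(texts: Iterable[str]) -> tuple[Counter, int]:
    """Count, per token, the number of documents containing it."""
    df: Counter = Counter()
    n = 0
    for text in texts:
        n += 1
        df.update(set(_TOKEN_RE.findall(text.lower())))
    return df, n


@dataclass(eq=False, frozen=True)
class Fingerprint:
    """A fixed-width binary vector identifying one document."""

    bits: np.ndarray  # uint8 vector of 0/1
    note_ref: str | None = None

    @property
    def width(self) -> int:
        return int(self.bits.shape[0])

    def to_hex(self) -> str:
        return np.packbits(self.bits).tobytes().hex()

    @classmethod
    def from_hex(cls, value: str, width: int, note_ref: str | None = None) -> "Fingerprint":
        raw = np.frombuffer(bytes.fromhex(value), dtype=np.uint8)
        return cls(bits=np.unpackbits(raw)[:width].copy(), note_ref=note_ref)


def _token_bits(token: str, width: int, hash_seed: int) -> np.ndarray:
    digest = hashlib.blake2b(
        token.encode("utf-8"),
        digest_size=width // 8,
        person=hash_seed.to_bytes(8, "little", signed=False),
    ).digest()
    return np.unpackbits(np.frombuffer(digest, dtype=np.uint8))


def simhash(
    bag: Mapping[str, float],
    bits: int = 64,
    hash_seed: int = 0,
    note_ref: str | None = None,
) -> Fingerprint:
    """Charikar SimHash of a weighted token bag.

    Deterministic for a fixed ``hash_seed`` (a keyed blake2b hash maps each
    token to ``bits`` bits, so fingerprints are stable across runs and
    platforms).  An empty bag yields the all-zero fingerprint.
    """
    if bits not in SUPPORTED_WIDTHS:
        raise ParameterError(f"unsupported fingerprint width {bits}; choose one of {SUPPORTED_WIDTHS}")
    acc = np.zeros(bits, dtype=np.float64)
    for token, weight in bag.items():
        bv = _token_bits(token, bits, hash_seed).astype(np.float64)
        acc += weight * (2.0 * bv - 1.0)
    return Fingerprint(bits=(acc > 0).astype(np.uint8), note_ref=note_ref)


def hamming(a: Fingerprint, b: Fingerprint) -> int:
    """Number of bit positions at which two equal-width fingerprints differ."""
    if a.width != b.width:
        raise ParameterError(f"fingerprint width mismatch: {a.width} vs {b.width}")
    return int(np.count_nonzero(a.bits != b.bits))


# ---------------------------------------------------------------------------
# sectioning (a document embedding can be replaced by a section embedding)

_SECTION_HEADER_RE = re.compile(r"^([A-Za-z][\w /-]{0,40}):")


def split_sections(text: str) -> dict[str, str]:
    """Split a note into sections on blank lines and ``Header:`` keywords.

    Returns a mapping from lowercased section name (the leading ``Header:``
    token of the block, or ``section_<i>`` when a block has no header) to the
    block's text.  Used when fingerprinting a representative text segment
    instead of the whole document.
    """
    blocks = [b for b in re.split(r"\n\s*\n", text) if b.strip()]
    sections: dict[str, str] = {}
    for i, block in enumerate(blocks):
        m = _SECTION_HEADER_RE.match(block.strip())
        name = m.group(1).strip().lower() if m else f"section_{i}"
        if name in sections:
            name = f"{name}_{i}"
        sections[name] = block.strip()
    return sections


def fingerprint_corpus(
    corpus: Corpus,
    bits: int = 64,
    weighting: str = "tf",
    hash_seed: int = 0,
    section: str | None = None,
) -> list[Fingerprint]:
    """Embed every note of a corpus into a fingerprint.

    ``weighting`` is ``"tf"`` or ``"tfidf"``; with ``section`` set, only the
    named section of each note is embedded (notes without that section fall
    back to their whole text).  Note references are the note_id, suffixed
    with ``#line_nbr`` when note_ids repeat in the corpus.
    """
    if weighting not in ("tf", "tfidf"):
        raise ParameterError(f"unknown weighting {weighting!r}")
    texts = []
    for n in corpus.notes:
        text = n.text
        if section is not None:
            text = split_sections(text).get(section, text)
        texts.append(text)
    df, ndocs = (None, None)
    if weighting == "tfidf":
        df, ndocs = document_frequencies(texts)
    ids = [n.note_id for n in corpus.notes]
    unique_ids = len(set(ids)) == len(ids)
    fps = []
    for n, text in zip(corpus.notes, texts):
        ref = n.note_id if unique_ids else f"{n.note_id}#{n.line_nbr}"
        fps.append(simhash(tokenize(text, df, ndocs), bits=bits, hash_seed=hash_seed, note_ref=ref))
    return fps


# ---------------------------------------------------------------------------
# clustering


@dataclass
class ClusterModel:
    """A fitted K-means partition of a fingerprint collection."""

    k: int
    assignments: dict[str, int]
    centroids: np.ndarray  # (k, B) per-bit means
    representatives: dict[int, str]
    objective: float
    n_iter: int
    objective_history: list[float] = field(default_factory=list)


def _check_refs(fps: Sequence[Fingerprint]) -> list[str]:
    refs = [fp.note_ref for fp in fps]
    if any(r is None for r in refs):
        raise ParameterError("every fingerprint must carry a note_ref for clustering")
    if len(set(refs)) != len(refs):
        raise ParameterError("fingerprint note_refs must be unique")
    return refs  # type: ignore[return-value]


def cluster_fingerprints(
    fps: Sequence[Fingerprint],
    k: int,
    seed: int = 0,
    max_iter: int = 100,
) -> ClusterModel:
    """Lloyd-style K-means over fingerprints viewed as points in {0,1}^B.

    Initialisation is farthest-point seeding from a seeded random start
    (k-means++ flavoured but deterministic given the seed).  The update step
    recomputes centroids as per-bit means; an emptied cluster is re-seeded
    with the point farthest from its current centroid.  The within-cluster
    squared-distance objective is recorded after every assignment step and
    is non-increasing across iterations.
    """
    n = len(fps)
    if k < 1:
        raise ParameterError(f"K must be >= 1, got {k}")
    if k > n:
        raise ParameterError(f"K = {k} exceeds the number of fingerprints ({n})")
    refs = _check_refs(fps)
    widths = {fp.width for fp in fps}
    if len(widths) != 1:
        raise ParameterError(f"mixed fingerprint widths {sorted(widths)}")
    X = np.stack([fp.bits for fp in fps]).astype(np.float64)

    rng = np.random.default_rng(seed)
    first = int(rng.integers(n))
    centers = [first]
    d2 = ((X - X[first]) ** 2).sum(axis=1)
    while len(centers) < k:
        j = int(np.argmax(d2))
        centers.append(j)
        d2 = np.minimum(d2, ((X - X[j]) ** 2).sum(axis=1))
    C = X[centers].copy()

    assign = np.full(n, -1, dtype=np.int64)
    history: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        D = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=-1)
        new_assign = D.argmin(axis=1)
        # re-seed emptied clusters with the globally worst-fitting point
        for j in range(k):
            if not np.any(new_assign == j):
                far = int(np.argmax(D[np.arange(n), new_assign]))
                C[j] = X[far]
                D[:, j] = ((X - C[j]) ** 2).sum(axis=1)
                new_assign = D.argmin(axis=1)
        history.append(float(D[np.arange(n), new_assign].sum()))
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            C[j] = X[assign == j].mean(axis=0)

    model = ClusterModel(
        k=k,
        assignments={refs[i]: int(assign[i]) for i in range(n)},
        centroids=C,
        representatives={},
        objective=history[-1],
        n_iter=n_iter,
        objective_history=history,
    )
    model.representatives = representatives(model, fps)
    return model


def representatives(model: ClusterModel, fps: Sequence[Fingerprint]) -> dict[int, str]:
    """Per cluster, the member note closest to the centroid.

    The representative is always an actual input note, never a synthetic
    centroid; ties break toward the lexicographically smallest note_ref.
    """
    by_ref = {fp.note_ref: fp for fp in fps}
    reps: dict[int, str] = {}
    for j in range(model.k):
        members = [ref for ref, c in model.assignments.items() if c == j]
        if not members:
            raise ParameterError(f"cluster {j} has no members; cannot pick a representative")
        best = min(
            members,
            key=lambda ref: (
                float(((by_ref[ref].bits.astype(np.float64) - model.centroids[j]) ** 2).sum()),
                ref,
            ),
        )
        reps[j] = best
    return reps
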