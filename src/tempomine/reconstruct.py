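"""Reconstruction of free text into time-stamped clinical-entity sequences.

The reconstruction algorithm proceeds in three steps.  (1) Each sentence is
tested for temporal intent — does it contain at least one temporal
expression?  (2) Sentences with temporal intent are decomposed into a
*non-temporal sub-expression* (the sentence with temporal spans excised)
plus a list of *temporal constraints* (normalized anchor times, durations,
cue words, ordinals).  (3) Similar sub-expressions are clustered into
entity labels with K-medoids over SimHash sentence fingerprints, so every
label is exemplified by a real sub-expression (its medoid).  The output is
a sequence database: per patient, an ordered list of (time, itemset)
events, pivotable between a per-time and a per-patient view.

The K-medoids here is PAM with a deterministic farthest-first
initialisation (first medoid = the 1-medoid optimum, subsequent medoids =
farthest-first) and Hamming distance over SimHash fingerprints of the
sub-expression token bags.  This keeps the procedure seeded-deterministic
and the exemplars real; it is an interpretive choice, documented in
docs/methods.md, since "modified K-medoids" admits several readings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .corpus import Corpus
from .errors import ConsistencyError, ModeError, OrderingError, ParameterError
from .fingerprint import Fingerprint, hamming, simhash, tokenize
from .timeline import TemporalExpression, TemporalLexicon, find_temporal_expressions

# ---------------------------------------------------------------------------
# domain types


@dataclass
class DecomposedExpression:
    """A sentence rewritten as non-temporal text plus temporal constraints."""

    sub_expression: str
    constraints: list[tuple[str, object]] = field(default_factory=list)
    source_note: str | None = None
    sentence_span: tuple[int, int] | None = None


@dataclass
class TimedEntity:
    """One clinical entity anchored in time for one patient."""

    patient_id: str
    entity_label: int | str
    exemplar: str | None = None
    cause: str | None = None
    anchor_time: object | None = None  # datetime or relative day offset
    duration_hours: float | None = None
    duration_days: int | None = None
    order_key: object | None = None
    source_note: str | None = None

    @property
    def item(self):
        """The symbol this entity contributes to a sequence itemset."""
        return self.exemplar if self.exemplar is not None else self.entity_label


@dataclass
class SequenceDatabase:
    """Per-patient ordered lists of (time_index, itemset) events.

    ``times`` holds the distinct time points t1..tm that the integer
    ``time_index`` values refer to; ``alphabet`` the sorted distinct item
    labels.  The canonical form is the per-patient view; the per-time view
    is a pivot of the same relation.
    """

    sequences: dict[str, list[tuple[int, tuple]]]
    times: list
    alphabet: tuple

    @property
    def patients(self) -> list[str]:
        return list(self.sequences)

    def item_sequences(self) -> dict[str, list[tuple]]:
        """Drop time indices: per patient, the ordered list of itemsets."""
        return {pid: [items for _, items in events] for pid, events in self.sequences.items()}

    def to_frame(self, view: str = "patient") -> pd.DataFrame:
        """Long-form relation with one row per (patient, time, item).

        ``view="patient"`` sorts by patient then time (the bottom half of a
        sequence-data table); ``view="time"`` sorts by time then patient
        (the top half).  Both views contain exactly the same rows.
        """
        if view not in ("patient", "time"):
            raise ParameterError(f"view must be 'patient' or 'time', got {view!r}")
        rows = []
        order = {pid: i for i, pid in enumerate(self.sequences)}
        for pid, events in self.sequences.items():
            for t_idx, items in events:
                for item in items:
                    rows.append(
                        {
                            "patient_id": pid,
                            "time_index": t_idx,
                            "time": self.times[t_idx] if self.times else t_idx,
                            "item": item,
                        }
                    )
        df = pd.DataFrame(rows, columns=["patient_id", "time_index", "time", "item"])
        if view == "patient":
            df = df.sort_values(
                by=["patient_id", "time_index", "item"],
                key=lambda s: s.map(order) if s.name == "patient_id" else s,
                kind="stable",
            )
        else:
            df = df.sort_values(
                by=["time_index", "patient_id", "item"],
                key=lambda s: s.map(order) if s.name == "patient_id" else s,
                kind="stable",
            )
        return df.reset_index(drop=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, times: list | None = None) -> "SequenceDatabase":
        """Rebuild a database from either long-form view (pivot inverse)."""
        if times is None:
            pairs = sorted({(int(r.time_index), r.time) for r in df.itertuples()})
            times = [t for _, t in pairs]
        sequences: dict[str, dict[int, set]] = {}
        for r in df.itertuples():
            sequences.setdefault(str(r.patient_id), {}).setdefault(int(r.time_index), set()).add(
                r.item
            )
        built = {
            pid: [(t, tuple(sorted(items, key=str))) for t, items in sorted(groups.items())]
            for pid, groups in sequences.items()
        }
        alphabet = tuple(sorted({i for ev in built.values() for _, items in ev for i in items}, key=str))
        return cls(sequences=built, times=list(times), alphabet=alphabet)

    def to_jsonl(self, path) -> None:
        import json

        with open(path, "w", encoding="utf-8") as fh:
            for pid, events in self.sequences.items():
                fh.write(
                    json.dumps(
                        {
                            "patient": pid,
                            "events": [
                                {
                                    "t": t,
                                    "time": (
                                        self.times[t].isoformat()
                                        if self.times and isinstance(self.times[t], datetime)
                                        else (self.times[t] if self.times else t)
                                    ),
                                    "items": [str(i) for i in items],
                                }
                                for t, items in events
                            ],
                        }
                    )
                    + "\n"
                )

    @classmethod
    def from_jsonl(cls, path) -> "SequenceDatabase":
        import json

        sequences: dict[str, list[tuple[int, tuple]]] = {}
        time_map: dict[int, object] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                rec = json.loads(line)
                events = []
                for ev in rec["events"]:
                    t = int(ev["t"])
                    time_map.setdefault(t, ev.get("time", t))
                    events.append((t, tuple(sorted(ev["items"], key=str))))
                sequences[rec["patient"]] = sorted(events)
        times = [time_map[t] for t in sorted(time_map)] if time_map else []
        alphabet = tuple(
            sorted({i for ev in sequences.values() for _, items in ev for i in items}, key=str)
        )
        return cls(sequences=sequences, times=times, alphabet=alphabet)


# ---------------------------------------------------------------------------
# step 2: decomposition

# small connectives that dangle once an adjacent explicit time span is excised
_CONNECTOR_RE = re.compile(
    r"(?:\b(?:for|at|on|in|over|from|to|of|by|x)\s*)$", re.IGNORECASE
)


def decompose(
    sentence: str,
    expressions: Sequence[TemporalExpression],
    source_note: str | None = None,
    sentence_span: tuple[int, int] | None = None,
) -> DecomposedExpression:
    """Rewrite a sentence into a non-temporal sub-expression + constraints.

    Temporal spans are excised (explicit spans also swallow an immediately
    preceding connective such as "for" or "from"); the remaining text is
    whitespace-normalized and stripped of dangling punctuation.  Each
    expression becomes one constraint, in span order:

    * explicit with a duration value   -> ``("duration", hours)``
    * explicit with a date/clock value -> ``("anchor_time", value)``
    * implicit signal                  -> ``("signal", surface)``
    * ordinal                          -> ``("ordinal", surface)``
    """
    cut: list[tuple[int, int]] = []
    constraints: list[tuple[str, object]] = []
    for ex in sorted(expressions, key=lambda e: e.start):
        if not (0 <= ex.start < ex.end <= len(sentence)):
            raise ConsistencyError(
                f"span {ex.span} out of bounds for sentence of length {len(sentence)}"
            )
        if sentence[ex.start : ex.end] != ex.surface:
            raise ConsistencyError(
                f"span {ex.span} does not reproduce surface {ex.surface!r}"
            )
        start = ex.start
        if ex.category == "explicit":
            m = _CONNECTOR_RE.search(sentence[:start])
            if m:
                start = m.start()
        cut.append((start, ex.end))
        if ex.category == "explicit":
            if isinstance(ex.normalized, (int, float)):
                constraints.append(("duration", float(ex.normalized)))
            elif ex.normalized is not None:
                constraints.append(("anchor_time", ex.normalized))
            else:
                constraints.append(("anchor_time", ex.surface))
        elif ex.category == "implicit_signal":
            constraints.append(("signal", ex.surface))
        else:
            constraints.append(("ordinal", ex.surface))

    kept = []
    pos = 0
    for s, e in cut:
        kept.append(sentence[pos:s])
        pos = max(pos, e)
    kept.append(sentence[pos:])
    text = re.sub(r"\s+", " ", " ".join(kept)).strip()
    text = re.sub(r"\s+([.,;:!?])", r"\1", text)
    text = text.strip(" .,;:!?-")
    return DecomposedExpression(
        sub_expression=text,
        constraints=constraints,
        source_note=source_note,
        sentence_span=sentence_span,
    )


def duration_between(start: datetime, end: datetime) -> tuple[int, int]:
    """Elapsed time between two instants on the two reporting scales.

    Returns ``(hours, days)`` where ``hours`` is the floor of the elapsed
    time in whole hours and ``days`` is the calendar-date difference.  An
    interval from 10:02 on one day to 04:26 two days later is therefore
    reported as 42 hours *or* 2 days — the two scales intentionally answer
    slightly different questions.
    """
    if end < start:
        raise OrderingError(f"end {end} precedes start {start}")
    hours = int((end - start).total_seconds() // 3600)
    days = (end.date() - start.date()).days
    return hours, days


# ---------------------------------------------------------------------------
# step 3: K-medoids over sub-expression fingerprints


@dataclass
class MedoidModel:
    """A fitted K-medoids partition of distinct sub-expressions."""

    labels: dict[str, int]  # sub_expression -> cluster label
    medoids: dict[int, str]  # cluster label -> exemplar sub_expression
    objective: float
    objective_history: list[float] = field(default_factory=list)


def _pairwise_hamming(fps: list[Fingerprint]) -> np.ndarray:
    X = np.stack([fp.bits for fp in fps]).astype(np.int16)
    return np.abs(X[:, None, :] - X[None, :, :]).sum(axis=-1)


def cluster_subexpressions(
    subs: Iterable[DecomposedExpression | str],
    k: int,
    seed: int = 0,
    bits: int = 64,
    hash_seed: int = 0,
    max_swaps: int = 200,
) -> MedoidModel:
    """PAM K-medoids over SimHash fingerprints of sub-expressions.

    Distinct sub-expression strings (first-appearance order) are embedded
    with SimHash of their lowercased token bags and partitioned under
    Hamming distance.  Initialisation is deterministic farthest-first: the
    first medoid minimises total distance to all points, each further
    medoid maximises the distance to its nearest chosen medoid.  The swap
    phase greedily applies the best improving (medoid, non-medoid) exchange
    until none improves the total within-cluster distance.  ``seed`` is
    accepted for interface symmetry; the procedure is deterministic
    regardless.
    """
    texts: list[str] = []
    seen = set()
    for s in subs:
        t = s.sub_expression if isinstance(s, DecomposedExpression) else str(s)
        if t not in seen:
            seen.add(t)
            texts.append(t)
    n = len(texts)
    if not 1 <= k <= n:
        raise ParameterError(f"K must be in [1, {n}] (distinct sub-expressions), got {k}")

    fps = [simhash(tokenize(t), bits=bits, hash_seed=hash_seed) for t in texts]
    D = _pairwise_hamming(fps)

    first = int(np.argmin(D.sum(axis=1)))
    medoids = [first]
    mind = D[first].copy()
    while len(medoids) < k:
        j = int(np.argmax(mind))
        medoids.append(j)
        mind = np.minimum(mind, D[j])

    def objective(meds: list[int]) -> float:
        return float(D[:, meds].min(axis=1).sum())

    history = [objective(medoids)]
    improved = True
    swaps = 0
    while improved and swaps < max_swaps:
        improved = False
        best = (history[-1], None)
        med_set = set(medoids)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in med_set:
                    continue
                cand = medoids[:mi] + [h] + medoids[mi + 1 :]
                obj = objective(cand)
                if obj < best[0] - 1e-12:
                    best = (obj, (mi, h))
        if best[1] is not None:
            mi, h = best[1]
            medoids[mi] = h
            history.append(best[0])
            improved = True
            swaps += 1

    assign = np.asarray(D[:, medoids]).argmin(axis=1)
    labels = {texts[i]: int(assign[i]) for i in range(n)}
    return MedoidModel(
        labels=labels,
        medoids={c: texts[medoids[c]] for c in range(k)},
        objective=history[-1],
        objective_history=history,
    )


# ---------------------------------------------------------------------------
# sequence building


def build_sequences(entities: Sequence[TimedEntity], mode: str = "timed") -> SequenceDatabase:
    """Group timed entities into a per-patient sequence database.

    ``timed`` mode requires an anchor time on every entity: the distinct
    anchor times across the whole collection become the global time points
    t1..tm, and same-time entities of one patient merge into one itemset.
    ``order_only`` mode (for de-identified corpora without usable
    timestamps) keeps only the relative order: entities sharing an
    ``order_key`` form one itemset, consecutive keys get consecutive
    indices per patient.
    """
    if mode not in ("timed", "order_only"):
        raise ParameterError(f"mode must be 'timed' or 'order_only', got {mode!r}")
    if mode == "timed":
        missing = [e for e in entities if e.anchor_time is None]
        if missing:
            raise ModeError(
                f"timed mode requires anchor times; {len(missing)} entities lack one "
                f"(first: patient {missing[0].patient_id!r})"
            )
        times = sorted({e.anchor_time for e in entities})
        index = {t: i for i, t in enumerate(times)}
        grouped: dict[str, dict[int, set]] = {}
        for e in entities:
            grouped.setdefault(e.patient_id, {}).setdefault(index[e.anchor_time], set()).add(e.item)
        sequences = {
            pid: [(t, tuple(sorted(items, key=str))) for t, items in sorted(groups.items())]
            for pid, groups in grouped.items()
        }
    else:
        sequences = {}
        per_patient: dict[str, dict[object, set]] = {}
        counters: dict[str, int] = {}
        for e in entities:
            groups = per_patient.setdefault(e.patient_id, {})
            key = e.order_key
            if key is None:
                key = ("__auto__", counters.get(e.patient_id, 0))
                counters[e.patient_id] = counters.get(e.patient_id, 0) + 1
            groups.setdefault(key, set()).add(e.item)
        max_len = 0
        for pid, groups in per_patient.items():
            events = [(i, tuple(sorted(items, key=str))) for i, items in enumerate(groups.values())]
            sequences[pid] = events
            max_len = max(max_len, len(events))
        times = list(range(max_len))
    alphabet = tuple(
        sorted({i for ev in sequences.values() for _, items in ev for i in items}, key=str)
    )
    return SequenceDatabase(sequences=sequences, times=list(times), alphabet=alphabet)


# ---------------------------------------------------------------------------
# corpus-level driver

_SENTENCE_RE = re.compile(r"[^.!?\n]+[.!?]?")

_CAUSE_RE = re.compile(
    r"(?P<cause>[\w][\w'’ -]{2,79}?)\s*(?:\(caused sepsis\)|caused sepsis)", re.IGNORECASE
)


def iter_sentences(text: str):
    """Yield (start, end, sentence) triples; naive punctuation splitting."""
    for m in _SENTENCE_RE.finditer(text):
        s = m.group(0)
        if s.strip():
            yield m.start(), m.end(), s


def extract_cause(text: str) -> str | None:
    """Pull a 'condition (caused sepsis)' attribution from the note header."""
    first_line = text.split("\n", 1)[0]
    m = _CAUSE_RE.search(first_line)
    return m.group("cause").strip() if m else None


def reconstruct_corpus(
    corpus: Corpus,
    k_entities: int = 8,
    seed: int = 0,
    bits: int = 64,
    hash_seed: int = 0,
    lexicon: TemporalLexicon | None = None,
) -> tuple[list[TimedEntity], MedoidModel]:
    """Run the full reconstruction over a corpus.

    Sentences without temporal intent are dropped; the rest are decomposed,
    their distinct sub-expressions clustered into at most ``k_entities``
    labels (capped at the number of distinct sub-expressions), and one
    :class:`TimedEntity` emitted per decomposed sentence, anchored at the
    note timestamp and carrying the first duration constraint (if any) plus
    the note-header cause attribution.
    """
    note_rank: dict[tuple[str, int], int] = {}
    for pid in corpus.patients():
        notes = [n for n in corpus.notes if n.patient_id == pid]
        if all(n.timestamp is not None for n in notes):
            notes = sorted(notes, key=lambda n: n.timestamp)
        for r, n in enumerate(notes):
            note_rank[(n.note_id, n.line_nbr)] = r

    pending: list[tuple] = []  # (note, rank, decomposed)
    for note in corpus.notes:
        cause = extract_cause(note.text)
        rank = note_rank[(note.note_id, note.line_nbr)]
        for s_start, s_end, sentence in iter_sentences(note.text):
            exprs = find_temporal_expressions(sentence, lexicon)
            if not exprs:
                continue
            dec = decompose(
                sentence,
                exprs,
                source_note=note.note_id,
                sentence_span=(s_start, s_end),
            )
            if not dec.sub_expression:
                continue
            pending.append((note, rank, cause, dec))

    if not pending:
        return [], MedoidModel(labels={}, medoids={}, objective=0.0)
    distinct = {dec.sub_expression for *_, dec in pending}
    k = min(k_entities, len(distinct))
    model = cluster_subexpressions(
        [dec for *_, dec in pending], k=k, seed=seed, bits=bits, hash_seed=hash_seed
    )

    entities: list[TimedEntity] = []
    for note, rank, cause, dec in pending:
        label = model.labels[dec.sub_expression]
        duration = next((v for kind, v in dec.constraints if kind == "duration"), None)
        entities.append(
            TimedEntity(
                patient_id=note.patient_id,
                entity_label=label,
                exemplar=model.medoids[label],
                cause=cause,
                anchor_time=note.timestamp,
                duration_hours=duration,
                order_key=rank,
                source_note=note.note_id,
            )
        )
    return entities, model
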