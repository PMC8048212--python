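"""PrefixSpan sequential pattern mining over reconstructed sequences.

Support is counted once per patient sequence (a pattern occurring twice in
one patient still counts 1), and a pattern is contained in a sequence when
its items appear in order at strictly increasing time steps.  The default
mining mode grows single-item chains — the shape of symptom-pattern reports
such as ``76 ['respiratory failure', 'hypoxemic respiratory', ...]`` —
through recursive projected-database growth, which enumerates the complete,
duplicate-free set of frequent ordered patterns.  An optional itemset mode
mines patterns whose elements are whole itemsets (several symptoms at one
time step); it uses exhaustive candidate growth with anti-monotone pruning,
which is slower but complete.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ParameterError


@dataclass(frozen=True)
class SequentialPattern:
    """An ordered pattern with its support count (a report's Freq column)."""

    items: tuple
    support: int

    def __len__(self) -> int:
        return sum(len(e) if isinstance(e, tuple) else 1 for e in self.items)


def _as_sequences(db) -> list[list[tuple]]:
    """Normalize the input to a list of sequences of itemset tuples."""
    if hasattr(db, "item_sequences"):
        raw = db.item_sequences().values()
    elif isinstance(db, Mapping):
        raw = db.values()
    else:
        raw = db
    seqs = []
    for seq in raw:
        norm = []
        for itemset in seq:
            if isinstance(itemset, (set, frozenset, tuple, list)):
                norm.append(tuple(sorted(itemset, key=str)))
            else:
                norm.append((itemset,))
        seqs.append(norm)
    return seqs


def prefixspan(
    db,
    min_support: int = 2,
    max_length: int | None = None,
    itemset_extensions: bool = False,
) -> list[SequentialPattern]:
    """Mine the complete set of ordered frequent patterns.

    Parameters
    ----------
    db:
        A :class:`~tempomine.reconstruct.SequenceDatabase`, a mapping from
        sequence id to a list of itemsets, or a bare list of sequences.
    min_support:
        Minimum number of distinct sequences that must contain a pattern.
    max_length:
        Cap on the total number of items in a pattern (None = unlimited).
    itemset_extensions:
        When True, pattern elements may be multi-item itemsets.
    """
    if min_support < 1:
        raise ParameterError(f"min_support must be >= 1, got {min_support}")
    seqs = _as_sequences(db)
    if not seqs:
        raise ParameterError("sequence database is empty")
    if itemset_extensions:
        return _mine_itemset_patterns(seqs, min_support, max_length)

    out: list[SequentialPattern] = []
    projections = [(sid, 0) for sid in range(len(seqs))]
    _mine_chains(seqs, projections, (), min_support, max_length, out)
    return out


def _mine_chains(seqs, projections, prefix, min_support, max_length, out):
    # first occurrence of each item at/after the projection point, per sequence
    occurrences: dict[object, list[tuple[int, int]]] = {}
    for sid, pos in projections:
        seen: dict[object, int] = {}
        for idx in range(pos, len(seqs[sid])):
            for item in seqs[sid][idx]:
                if item not in seen:
                    seen[item] = idx
        for item, idx in seen.items():
            occurrences.setdefault(item, []).append((sid, idx))

    for item in sorted(occurrences, key=str):
        occ = occurrences[item]
        if len(occ) < min_support:
            continue
        pattern = prefix + (item,)
        out.append(SequentialPattern(items=pattern, support=len(occ)))
        if max_length is None or len(pattern) < max_length:
            _mine_chains(
                seqs,
                [(sid, idx + 1) for sid, idx in occ],
                pattern,
                min_support,
                max_length,
                out,
            )


# ---------------------------------------------------------------------------
# itemset-element mining (flagged mode)


def _contains(seq: list[tuple], pattern: tuple[tuple, ...]) -> bool:
    """Greedy subsequence containment with subset matching per element."""
    idx = 0
    for element in pattern:
        wanted = set(element)
        while idx < len(seq) and not wanted.issubset(seq[idx]):
            idx += 1
        if idx == len(seq):
            return False
        idx += 1
    return True


def _support(seqs, pattern) -> int:
    return sum(1 for seq in seqs if _contains(seq, pattern))


def _mine_itemset_patterns(seqs, min_support, max_length):
    items = sorted({i for seq in seqs for itemset in seq for i in itemset}, key=str)
    frequent_items = [
        i for i in items if sum(1 for seq in seqs if any(i in s for s in seq)) >= min_support
    ]
    out: list[SequentialPattern] = []

    def grow(pattern: tuple[tuple, ...], size: int):
        # sequence extensions: append a new single-item element
        for i in frequent_items:
            cand = pattern + ((i,),)
            sup = _support(seqs, cand)
            if sup >= min_support:
                out.append(SequentialPattern(items=cand, support=sup))
                if max_length is None or size + 1 < max_length:
                    grow(cand, size + 1)
        # itemset extensions: enlarge the last element (canonical order)
        if pattern:
            last = pattern[-1]
            for i in frequent_items:
                if str(i) <= str(last[-1]):
                    continue
                cand = pattern[:-1] + (last + (i,),)
                sup = _support(seqs, cand)
                if sup >= min_support:
                    out.append(SequentialPattern(items=cand, support=sup))
                    if max_length is None or size + 1 < max_length:
                        grow(cand, size + 1)

    grow((), 0)
    return out


# ---------------------------------------------------------------------------
# reporting


def _sort_key(p: SequentialPattern):
    return (-p.support, -len(p), tuple(str(e) for e in p.items))


def flatten_items(pattern: SequentialPattern) -> tuple:
    flat = []
    for e in pattern.items:
        if isinstance(e, tuple):
            flat.extend(e)
        else:
            flat.append(e)
    return tuple(flat)


def top_k_report(patterns: Iterable[SequentialPattern], k: int) -> list[tuple[int, tuple]]:
    """The k highest-support patterns as (Freq, Pattern) rows.

    Sorted by support descending; ties go to the longer pattern, then
    lexicographic order of the items.
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    ordered = sorted(patterns, key=_sort_key)
    return [(p.support, p.items) for p in ordered[:k]]


def format_report(rows: Sequence[tuple[int, tuple]]) -> str:
    """Render report rows as a Freq/Pattern text table."""
    lines = ["Freq  Pattern"]
    for freq, items in rows:
        rendered = [list(e) if isinstance(e, tuple) else e for e in items]
        lines.append(f"{freq:<6}{rendered!r}")
    return "\n".join(lines)


def filter_patterns(
    patterns: Iterable[SequentialPattern],
    min_length: int = 1,
    required_items: Iterable | None = None,
) -> list[SequentialPattern]:
    """Keep patterns with at least ``min_length`` items containing all
    ``required_items`` (matched against the flattened item list)."""
    required = set(required_items or ())
    return [
        p for p in patterns if len(p) >= min_length and required.issubset(set(flatten_items(p)))
    ]
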