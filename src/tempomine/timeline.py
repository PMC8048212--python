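"""External-timeline alignment and internal-timeline temporal expressions.

A clinical corpus carries (at least) two timelines.  The *external* timeline
orders whole notes chronologically per patient, anchored to a terminal event
(death or discharge); expressing note times as signed offsets from the
anchor lets notes of many patients be pooled at equal offsets, which
enlarges training sets for downstream models.  The *internal* timeline
lives inside the free text and is recovered by detecting temporal
expressions of three categories:

``explicit``
    dates, clock times and duration phrases ("2 days", "42 h"), including
    the masked de-identification dialect in which a date is printed as the
    literal ``DD-MM-YYYY`` (an unknown but fixed reference date) optionally
    prefixed ``+ n`` for "reference date plus n calendar days";
``implicit_signal``
    cue words for temporal relations (before, after, since, ...);
``ordinal``
    ordinal words (first, second, initially, ...).

The cue-word and ordinal lexicons ship as editable plain-text files under
``tempomine/data``; the built-in lists are a documented stand-in, not an
exhaustive clinical lexicon.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import datetime, time, timedelta
from importlib import resources
from pathlib import Path

from .corpus import Corpus, ClinicalNote
from .errors import AlignmentError, ParameterError

CATEGORIES = ("explicit", "implicit_signal", "ordinal")

#: The fixed but unknown reference date that the masked-date literal
#: ``DD-MM-YYYY`` stands for.  Durations between masked dates are well
#: defined even though the absolute date is not.
MASKED_DATE_EPOCH = datetime(2000, 1, 1)


@dataclass(frozen=True)
class TemporalExpression:
    """One temporal expression located in a note's text.

    ``start``/``end`` are 0-based half-open character offsets; ``surface``
    always equals ``text[start:end]``.  ``normalized`` is a datetime for
    dates, a :class:`datetime.time` for bare clock times, a duration in
    hours (float) for duration phrases, and ``None`` for cue/ordinal words.
    """

    start: int
    end: int
    category: str
    surface: str
    normalized: object | None = None

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class AlignedNote:
    """A note placed on the external timeline relative to an anchor event."""

    note: ClinicalNote
    anchor: str  # "death" | "discharge"
    offset_hours: float  # note time minus anchor time


# ---------------------------------------------------------------------------
# lexicons


def _load_wordlist(path) -> tuple[str, ...]:
    words = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.append(line.lower())
    return tuple(words)


@dataclass(frozen=True)
class TemporalLexicon:
    """Cue-word and ordinal lexicons used by the expression finder."""

    cues: tuple[str, ...]
    ordinals: tuple[str, ...]

    @classmethod
    def default(cls) -> "TemporalLexicon":
        data = resources.files("tempomine") / "data"
        return cls(
            cues=_load_wordlist(data / "cue_words.txt"),
            ordinals=_load_wordlist(data / "ordinals.txt"),
        )

    @classmethod
    def from_dir(cls, directory: str | Path) -> "TemporalLexicon":
        directory = Path(directory)
        return cls(
            cues=_load_wordlist(directory / "cue_words.txt"),
            ordinals=_load_wordlist(directory / "ordinals.txt"),
        )

    def phrase_regex(self, phrases: tuple[str, ...]) -> re.Pattern:
        ordered = sorted(phrases, key=len, reverse=True)
        return re.compile(
            r"\b(?:" + "|".join(re.escape(p) for p in ordered) + r")\b", re.IGNORECASE
        )


_DEFAULT_LEXICON: TemporalLexicon | None = None


def default_lexicon() -> TemporalLexicon:
    global _DEFAULT_LEXICON
    if _DEFAULT_LEXICON is None:
        _DEFAULT_LEXICON = TemporalLexicon.default()
    return _DEFAULT_LEXICON


# ---------------------------------------------------------------------------
# explicit-expression patterns

_MASKED_DATE_RE = re.compile(
    r"(?:\+\s*(?P<days>\d+)\s+)?DD-MM-YYYY(?:\s+(?P<hh>[01]?\d|2[0-3]):(?P<mm>[0-5]\d))?"
)
_ISO_DATE_RE = re.compile(r"\b(\d{4})-(\d{2})-(\d{2})\b")
_CLOCK_RE = re.compile(r"\b(?P<hh>[01]?\d|2[0-3]):(?P<mm>[0-5]\d)\b")
_DURATION_RE = re.compile(
    r"\b(?P<value>\d+(?:\.\d+)?)\s*(?P<unit>days?|d|weeks?|wks?|hours?|hrs?|hr|h|minutes?|mins?|min)\b",
    re.IGNORECASE,
)

_UNIT_HOURS = {
    "d": 24.0,
    "day": 24.0,
    "days": 24.0,
    "week": 168.0,
    "weeks": 168.0,
    "wk": 168.0,
    "wks": 168.0,
    "h": 1.0,
    "hr": 1.0,
    "hrs": 1.0,
    "hour": 1.0,
    "hours": 1.0,
    "min": 1 / 60,
    "mins": 1 / 60,
    "minute": 1 / 60,
    "minutes": 1 / 60,
}


def duration_to_hours(value: float, unit: str) -> float:
    try:
        return value * _UNIT_HOURS[unit.lower()]
    except KeyError as exc:
        raise ParameterError(f"unknown duration unit {unit!r}") from exc


def _explicit_candidates(text: str):
    for m in _MASKED_DATE_RE.finditer(text):
        days = int(m.group("days") or 0)
        norm = MASKED_DATE_EPOCH + timedelta(days=days)
        if m.group("hh") is not None:
            norm = norm.replace(hour=int(m.group("hh")), minute=int(m.group("mm")))
        yield (m.start(), m.end(), "explicit", norm)
    for m in _ISO_DATE_RE.finditer(text):
        try:
            norm = datetime(int(m.group(1)), int(m.group(2)), int(m.group(3)))
        except ValueError:
            continue
        yield (m.start(), m.end(), "explicit", norm)
    for m in _CLOCK_RE.finditer(text):
        yield (m.start(), m.end(), "explicit", time(int(m.group("hh")), int(m.group("mm"))))
    for m in _DURATION_RE.finditer(text):
        yield (
            m.start(),
            m.end(),
            "explicit",
            duration_to_hours(float(m.group("value")), m.group("unit")),
        )


_PRIORITY = {"explicit": 0, "implicit_signal": 1, "ordinal": 2}


def find_temporal_expressions(
    text: str, lexicon: TemporalLexicon | None = None
) -> list[TemporalExpression]:
    """Locate all temporal expressions in ``text``.

    Returns non-overlapping spans sorted by start offset; where candidate
    matches overlap, the longest match wins (explicit beats implicit beats
    ordinal on equal length).
    """
    lex = lexicon or default_lexicon()
    candidates: list[tuple[int, int, str, object | None]] = list(_explicit_candidates(text))
    if lex.cues:
        for m in lex.phrase_regex(lex.cues).finditer(text):
            candidates.append((m.start(), m.end(), "implicit_signal", None))
    if lex.ordinals:
        for m in lex.phrase_regex(lex.ordinals).finditer(text):
            candidates.append((m.start(), m.end(), "ordinal", None))

    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0], _PRIORITY[c[2]]))
    chosen: list[tuple[int, int, str, object | None]] = []
    for cand in candidates:
        if all(cand[1] <= s or cand[0] >= e for s, e, *_ in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda c: c[0])
    return [
        TemporalExpression(start=s, end=e, category=cat, surface=text[s:e], normalized=norm)
        for s, e, cat, norm in chosen
    ]


def has_temporal_intent(text: str, lexicon: TemporalLexicon | None = None) -> bool:
    """True iff the text contains at least one temporal expression."""
    return len(find_temporal_expressions(text, lexicon)) > 0


# ---------------------------------------------------------------------------
# external timeline


def align_external(corpus: Corpus, anchor: str = "discharge") -> list[AlignedNote]:
    """Place every note on the external timeline relative to ``anchor``.

    ``offset_hours`` is the signed difference (note timestamp minus anchor
    time) in hours, so notes written before the anchor event have negative
    offsets.  Output is grouped by patient (order of first appearance) and
    sorted ascending by offset within each patient.
    """
    if anchor not in ("death", "discharge"):
        raise ParameterError(f"anchor must be 'death' or 'discharge', got {anchor!r}")
    attr = "death_time" if anchor == "death" else "discharge_time"
    missing = sorted(
        {
            n.patient_id
            for n in corpus.notes
            if corpus.anchor_times.get(n.patient_id) is None
            or getattr(corpus.anchor_times[n.patient_id], attr) is None
        }
    )
    if missing:
        raise AlignmentError(f"missing {anchor} time for patients: {', '.join(missing)}")
    for n in corpus.notes:
        if n.timestamp is None:
            raise AlignmentError(
                f"note {n.note_id!r} (line {n.line_nbr}) has no timestamp and cannot be aligned"
            )
    aligned: list[AlignedNote] = []
    by_patient: dict[str, list[AlignedNote]] = {}
    for n in corpus.notes:
        anchor_time = getattr(corpus.anchor_times[n.patient_id], attr)
        offset = (n.timestamp - anchor_time).total_seconds() / 3600.0
        by_patient.setdefault(n.patient_id, []).append(
            AlignedNote(note=n, anchor=anchor, offset_hours=offset)
        )
    for pid in corpus.patients():
        aligned.extend(sorted(by_patient[pid], key=lambda a: a.offset_hours))
    return aligned
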