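"""Reading, validating, deduplicating and merging clinical-note corpora.

A corpus is a flat collection of note records, one per (note_id, line_nbr)
pair.  Clinical data warehouses commonly re-emit a note every time it is
edited, incrementing a line counter while keeping the note identifier, so
the raw extract contains near-duplicate rows; :func:`deduplicate` keeps only
the most recent version of each note per patient.  :func:`merge_adjacent`
concatenates a patient's temporally adjacent notes into a single document,
which is useful before document-level fingerprinting.

Supported on-disk formats are RFC-4180 CSV and JSON-lines (UTF-8), with a
canonical header of ``note_id, line_nbr, patient_id, provider_id, note_type,
timestamp, text``.  A column mapping can be supplied for corpora that use a
different dialect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path

import pandas as pd

from .errors import ParameterError, SchemaError, TimestampParseError

NOTE_TYPES = ("nursing", "physician_progress", "discharge", "other")

CANONICAL_COLUMNS = (
    "note_id",
    "line_nbr",
    "patient_id",
    "provider_id",
    "note_type",
    "timestamp",
    "text",
)

REQUIRED_COLUMNS = ("note_id", "line_nbr", "patient_id", "text")

#: Timestamps are stored timezone-naive at minute precision.
TIMESTAMP_FORMAT = "%Y-%m-%d %H:%M"

_TIMESTAMP_FORMATS = (
    "%Y-%m-%d %H:%M",
    "%Y-%m-%dT%H:%M",
    "%Y-%m-%d %H:%M:%S",
    "%Y-%m-%dT%H:%M:%S",
    "%Y-%m-%d",
)


@dataclass
class ClinicalNote:
    """One note record with header metadata and free text."""

    note_id: str
    line_nbr: int
    patient_id: str
    text: str
    provider_id: str | None = None
    note_type: str = "other"
    timestamp: datetime | None = None


@dataclass
class PatientAnchors:
    """Anchor events for the external timeline of one patient."""

    death_time: datetime | None = None
    discharge_time: datetime | None = None


@dataclass
class Corpus:
    """An ordered collection of :class:`ClinicalNote` plus per-patient anchors."""

    notes: list[ClinicalNote] = field(default_factory=list)
    name: str = ""
    anchor_times: dict[str, PatientAnchors] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.notes)

    def __iter__(self):
        return iter(self.notes)

    def patients(self) -> list[str]:
        """Patient identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for n in self.notes:
            seen.setdefault(n.patient_id, None)
        return list(seen)

    def validate(self) -> None:
        """Raise :class:`SchemaError` if any corpus invariant is violated."""
        keys: set[tuple[str, int]] = set()
        for i, n in enumerate(self.notes):
            if not n.note_id:
                raise SchemaError(f"empty note_id in record {i}")
            if not n.patient_id:
                raise SchemaError(f"empty patient_id in record {i}")
            if n.line_nbr < 1:
                raise SchemaError(f"line_nbr must be >= 1, got {n.line_nbr} in record {i}")
            if n.note_type not in NOTE_TYPES:
                raise SchemaError(f"unknown note_type {n.note_type!r} in record {i}")
            key = (n.note_id, n.line_nbr)
            if key in keys:
                raise SchemaError(f"duplicate (note_id, line_nbr) pair {key} in record {i}")
            keys.add(key)


def parse_timestamp(value: str) -> datetime:
    """Parse a timestamp string to a tz-naive datetime at minute precision."""
    for fmt in _TIMESTAMP_FORMATS:
        try:
            return datetime.strptime(value, fmt).replace(second=0, microsecond=0)
        except ValueError:
            continue
    try:
        ts = pd.Timestamp(value)
    except (ValueError, TypeError) as exc:
        raise TimestampParseError(f"unparseable timestamp {value!r}") from exc
    if pd.isna(ts):
        raise TimestampParseError(f"unparseable timestamp {value!r}")
    return ts.to_pydatetime().replace(second=0, microsecond=0, tzinfo=None)


def format_timestamp(ts: datetime | None) -> str:
    return "" if ts is None else ts.strftime(TIMESTAMP_FORMAT)


def _note_from_record(record: dict, index: int) -> ClinicalNote:
    for col in REQUIRED_COLUMNS:
        value = record.get(col)
        if value is None or str(value).strip() == "":
            # note text may legitimately be whitespace-free but must exist
            if col == "text" and value == "":
                continue
            raise SchemaError(f"missing required field '{col}' in record {index}")
    try:
        line_nbr = int(str(record["line_nbr"]))
    except ValueError as exc:
        raise SchemaError(
            f"invalid line_nbr {record['line_nbr']!r} in record {index}"
        ) from exc
    raw_ts = record.get("timestamp")
    timestamp = None
    if raw_ts is not None and str(raw_ts).strip() != "":
        timestamp = parse_timestamp(str(raw_ts))
    provider = record.get("provider_id")
    provider_id = None if provider is None or str(provider) == "" else str(provider)
    note_type = record.get("note_type")
    note_type = "other" if note_type is None or str(note_type) == "" else str(note_type)
    return ClinicalNote(
        note_id=str(record["note_id"]),
        line_nbr=line_nbr,
        patient_id=str(record["patient_id"]),
        text=str(record["text"]),
        provider_id=provider_id,
        note_type=note_type,
        timestamp=timestamp,
    )


def read_corpus(
    path: str | Path,
    format: str = "csv",
    columns: dict[str, str] | None = None,
    name: str | None = None,
) -> Corpus:
    """Read a corpus from ``path``.

    Parameters
    ----------
    path:
        Input file.
    format:
        ``"csv"`` or ``"jsonl"``.
    columns:
        Optional mapping from canonical column names to the names used in the
        file (for corpora with a non-canonical header dialect).
    name:
        Corpus name; defaults to the file stem.
    """
    path = Path(path)
    if format not in ("csv", "jsonl"):
        raise ParameterError(f"unsupported corpus format {format!r}")
    rename = {v: k for k, v in (columns or {}).items()}

    records: list[dict] = []
    if format == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        if rename:
            df = df.rename(columns=rename)
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing required column '{col}'")
        records = df.to_dict(orient="records")
    else:
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                if not line.strip():
                    continue
                rec = json.loads(line)
                if rename:
                    rec = {rename.get(k, k): v for k, v in rec.items()}
                records.append(rec)

    notes = [_note_from_record(rec, i) for i, rec in enumerate(records)]
    corpus = Corpus(notes=notes, name=name if name is not None else path.stem)
    corpus.validate()
    return corpus


def write_corpus(corpus: Corpus, path: str | Path, format: str = "csv") -> Path:
    """Write ``corpus`` to ``path`` in the canonical header dialect."""
    path = Path(path)
    if format not in ("csv", "jsonl"):
        raise ParameterError(f"unsupported corpus format {format!r}")
    if format == "csv":
        df = pd.DataFrame(
            [
                {
                    "note_id": n.note_id,
                    "line_nbr": n.line_nbr,
                    "patient_id": n.patient_id,
                    "provider_id": n.provider_id or "",
                    "note_type": n.note_type,
                    "timestamp": format_timestamp(n.timestamp),
                    "text": n.text,
                }
                for n in corpus.notes
            ],
            columns=list(CANONICAL_COLUMNS),
        )
        df.to_csv(path, index=False)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            for n in corpus.notes:
                fh.write(
                    json.dumps(
                        {
                            "note_id": n.note_id,
                            "line_nbr": n.line_nbr,
                            "patient_id": n.patient_id,
                            "provider_id": n.provider_id,
                            "note_type": n.note_type,
                            "timestamp": format_timestamp(n.timestamp) or None,
                            "text": n.text,
                        }
                    )
                    + "\n"
                )
    return path


def load_anchor_times(path: str | Path) -> dict[str, PatientAnchors]:
    """Load per-patient anchor events from a JSON file."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    anchors = {}
    for pid, rec in raw.items():
        anchors[pid] = PatientAnchors(
            death_time=parse_timestamp(rec["death"]) if rec.get("death") else None,
            discharge_time=parse_timestamp(rec["discharge"]) if rec.get("discharge") else None,
        )
    return anchors


def save_anchor_times(anchors: dict[str, PatientAnchors], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {
                pid: {
                    "death": format_timestamp(a.death_time) or None,
                    "discharge": format_timestamp(a.discharge_time) or None,
                }
                for pid, a in anchors.items()
            },
            fh,
            indent=1,
        )
    return path


def deduplicate(corpus: Corpus) -> Corpus:
    """Keep, per (patient_id, note_id), only the note with maximal line_nbr.

    Repeated note rows arise when a note is re-signed or appended to: the
    note identifier stays fixed and the line counter grows, so the maximal
    line number is the most recent version of that note for the encounter.
    Relative order of the surviving notes is preserved.  Idempotent.
    """
    best: dict[tuple[str, str], tuple[int, ClinicalNote]] = {}
    for idx, n in enumerate(corpus.notes):
        key = (n.patient_id, n.note_id)
        if key not in best or n.line_nbr > best[key][1].line_nbr:
            best[key] = (idx, n)
    survivors = [n for _, n in sorted(best.values(), key=lambda t: t[0])]
    return Corpus(notes=survivors, name=corpus.name, anchor_times=dict(corpus.anchor_times))


def merge_adjacent(corpus: Corpus, gap_hours: float = 24.0) -> Corpus:
    """Concatenate per-patient notes whose consecutive time gaps are small.

    Notes of one patient are sorted by timestamp; runs of notes where each
    consecutive gap is at most ``gap_hours`` are joined into a single note
    (texts concatenated with a newline) carrying the earliest timestamp, the
    first note's note_id and ``line_nbr = 1``.  Notes of different patients
    never merge.  All notes must carry timestamps.
    """
    if gap_hours <= 0:
        raise ParameterError(f"gap_hours must be > 0, got {gap_hours}")
    for n in corpus.notes:
        if n.timestamp is None:
            raise ParameterError(
                f"note {n.note_id!r} (line {n.line_nbr}) has no timestamp; "
                "merge_adjacent requires timestamps on every note"
            )
    by_patient: dict[str, list[tuple[int, ClinicalNote]]] = {}
    for idx, n in enumerate(corpus.notes):
        by_patient.setdefault(n.patient_id, []).append((idx, n))

    merged: list[ClinicalNote] = []
    for pid in corpus.patients():
        entries = sorted(by_patient[pid], key=lambda t: (t[1].timestamp, t[0]))
        chain: list[ClinicalNote] = []
        for _, note in entries:
            if chain and (note.timestamp - chain[-1].timestamp).total_seconds() <= gap_hours * 3600:
                chain.append(note)
            else:
                if chain:
                    merged.append(_merge_chain(chain))
                chain = [note]
        if chain:
            merged.append(_merge_chain(chain))
    return Corpus(notes=merged, name=corpus.name, anchor_times=dict(corpus.anchor_times))


def _merge_chain(chain: list[ClinicalNote]) -> ClinicalNote:
    if len(chain) == 1:
        return replace(chain[0])
    first = chain[0]
    return replace(
        first,
        line_nbr=1,
        text="\n".join(n.text for n in chain),
        timestamp=min(n.timestamp for n in chain),
    )
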