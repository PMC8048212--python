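"""Seeded generator of synthetic sepsis-note corpora with known ground truth.

Real sepsis note corpora live behind institutional or credentialed access,
so every stage of the toolkit is exercised against generated corpora whose
planted structure is recorded exactly: note duplication (same note_id,
incremented line_nbr), per-patient timelines, temporal expressions of the
three categories, and ordered symptom patterns planted across a patient's
notes.  The generator emulates short templated nursing / physician /
discharge notes around a sepsis symptom vocabulary; it does not attempt
clinically realistic language, only the structural properties the toolkit
consumes.

Symptom sentences are written so that excising the temporal span leaves
exactly the symptom phrase (e.g. "fever for 2 days." -> "fever"), which
makes the planted entity vocabulary recoverable by the reconstruction
pipeline without hand-tuned matching.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

from .corpus import ClinicalNote, Corpus, PatientAnchors
from .errors import ValidationError
from .timeline import TemporalLexicon, find_temporal_expressions

DEFAULT_SYMPTOMS = (
    "fever",
    "hypotension",
    "respiratory failure",
    "hypoxemic respiratory",
    "tachycardia",
    "tachypnoea",
    "altered mental status",
    "hypothermia",
    "leukocytosis",
    "purulent drainage",
)

DEFAULT_CAUSES = (
    "Non-Hodgkin lymphoma",
    "Pneumonia",
    "Urinary tract infection",
    "Cellulitis",
    "Endocarditis",
)

#: Three ordered symptom patterns planted (independently per patient) with
#: high probability; symptoms are disjoint across patterns so supports stay
#: interpretable.
DEFAULT_PLANTED_PATTERNS = (
    (("fever", "hypotension"), 0.9),
    (("respiratory failure", "hypoxemic respiratory"), 0.9),
    (("tachypnoea", "altered mental status"), 0.9),
)

# Boilerplate deliberately free of temporal vocabulary so that planted
# temporal-expression counts are exact.
DEFAULT_TEMPLATES = (
    "{cause_line}Routine nursing assessment documented.\n{symptom_block}Will continue current plan.",
    "{cause_line}Patient seen and examined.\n{symptom_block}Plan reviewed with team.",
    "{cause_line}Vitals recorded, patient resting.\n{symptom_block}No acute events otherwise.",
    "{cause_line}Bedside evaluation completed.\n{symptom_block}Family updated at bedside.",
    "{cause_line}Systems review unremarkable apart from the above.\n{symptom_block}Continue antibiotics per protocol.",
    "{cause_line}Nursing flowsheet reconciled.\n{symptom_block}Care goals unchanged.",
    "{cause_line}Physician progress note.\n{symptom_block}Assessment discussed with attending.",
    "{cause_line}Discharge planning in progress.\n{symptom_block}Case management consulted.",
    "{cause_line}Patient tolerating current regimen.\n{symptom_block}Labs pending review.",
    "{cause_line}Overnight events charted by covering staff.\n{symptom_block}Plan per primary team.",
)

_ABBREVIATIONS = {
    "patient": "pt",
    "with": "w/",
    "without": "w/o",
    "history": "hx",
    "temperature": "temp",
    "respiratory": "resp",
    "assessment": "assess",
}


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic corpus."""

    n_patients: int = 20
    notes_per_patient: tuple[int, int] = (3, 6)
    duplicate_rate: float = 0.15
    template_bank: tuple[str, ...] = DEFAULT_TEMPLATES
    symptom_vocabulary: tuple[str, ...] = DEFAULT_SYMPTOMS
    cause_vocabulary: tuple[str, ...] = DEFAULT_CAUSES
    planted_patterns: tuple[tuple[tuple[str, ...], float], ...] = DEFAULT_PLANTED_PATTERNS
    temporal_mix: dict = field(
        default_factory=lambda: {"explicit": 0.4, "implicit_signal": 0.3, "ordinal": 0.3}
    )
    filler_rate: float = 0.35
    cause_line_rate: float = 0.5
    death_rate: float = 0.25
    time_origin: datetime = datetime(2019, 1, 1, 8, 0)
    inter_note_gap_hours: tuple[float, float] = (6.0, 48.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValidationError("n_patients must be >= 0")
        for name in ("duplicate_rate", "filler_rate", "cause_line_rate", "death_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be a probability in [0, 1], got {v}")
        for name in ("notes_per_patient", "inter_note_gap_hours"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"{name}: min {lo} exceeds max {hi}")
        if self.notes_per_patient[0] < 1:
            raise ValidationError("notes_per_patient minimum must be >= 1")
        if self.inter_note_gap_hours[0] <= 0:
            raise ValidationError("inter_note_gap_hours minimum must be > 0")
        for cat, p in self.temporal_mix.items():
            if cat not in ("explicit", "implicit_signal", "ordinal"):
                raise ValidationError(f"temporal_mix: unknown category {cat!r}")
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"temporal_mix[{cat!r}] must be in [0, 1], got {p}")
        for pattern, p in self.planted_patterns:
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"planted_patterns: probability {p} not in [0, 1]")
            unknown = [s for s in pattern if s not in self.symptom_vocabulary]
            if unknown:
                raise ValidationError(
                    f"planted_patterns: symptoms {unknown} not in symptom_vocabulary"
                )


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed to emitted notes."""

    #: (note_id, line_nbr) -> list of (surface, category, normalized_hours_or_None)
    temporal: dict[tuple[str, int], list[tuple[str, str, object]]] = field(default_factory=dict)
    #: patient -> chronological list of (timestamp, symptom)
    symptom_sequences: dict[str, list[tuple[datetime, str]]] = field(default_factory=dict)
    #: (patient_id, note_id) -> retained (maximal) line_nbr, duplicated notes only
    duplicates: dict[tuple[str, str], int] = field(default_factory=dict)
    #: (patient_id, planted ordered symptom tuple)
    pattern_instances: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)
    #: patient -> cause phrase used on the header line (if any)
    causes: dict[str, str] = field(default_factory=dict)


def _symptom_sentence(symptom: str, category: str, rng: random.Random):
    """One sentence mentioning ``symptom`` with a planted temporal expression.

    Returns (sentence, (surface, category, normalized)).
    """
    if category == "explicit":
        if rng.random() < 0.5:
            n = rng.randint(1, 4)
            unit = "days" if n != 1 else "day"
            surface = f"{n} {unit}"
            return f"{symptom} for {surface}.", (surface, "explicit", 24.0 * n)
        h = rng.randint(2, 96)
        surface = f"{h} h"
        return f"{symptom} for {surface}.", (surface, "explicit", float(h))
    if category == "implicit_signal":
        cue = rng.choice(("Then", "Subsequently"))
        return f"{cue} {symptom}.", (cue, "implicit_signal", None)
    word = rng.choice(("First", "Initially"))
    return f"{word} {symptom}.", (word, "ordinal", None)


def generate(config: GeneratorConfig) -> tuple[Corpus, GroundTruth]:
    """Emit a synthetic corpus and the exact record of what was planted."""
    config.validate()
    rng = random.Random(config.seed)
    truth = GroundTruth()
    notes: list[ClinicalNote] = []
    anchors: dict[str, PatientAnchors] = {}
    note_counter = 0

    planted_symptoms = {s for pattern, _ in config.planted_patterns for s in pattern}
    filler_pool = [s for s in config.symptom_vocabulary if s not in planted_symptoms]
    categories = list(config.temporal_mix)
    weights = [config.temporal_mix[c] for c in categories]
    note_types = ("nursing", "physician_progress", "discharge")

    for p in range(config.n_patients):
        pid = f"P{p:03d}"
        n_notes = rng.randint(*config.notes_per_patient)
        ts = config.time_origin
        timestamps = []
        for _ in range(n_notes):
            ts = ts + timedelta(hours=rng.uniform(*config.inter_note_gap_hours))
            timestamps.append(ts.replace(second=0, microsecond=0))

        # plant ordered patterns at strictly increasing note positions
        assigned: dict[int, list[str]] = {j: [] for j in range(n_notes)}
        for pattern, prob in config.planted_patterns:
            if len(pattern) <= n_notes and rng.random() < prob:
                positions = sorted(rng.sample(range(n_notes), len(pattern)))
                for pos, symptom in zip(positions, pattern):
                    assigned[pos].append(symptom)
                truth.pattern_instances.append((pid, tuple(pattern)))

        cause = rng.choice(config.cause_vocabulary)
        use_cause = rng.random() < config.cause_line_rate
        if use_cause:
            truth.causes[pid] = cause
        truth.symptom_sequences[pid] = []

        for j in range(n_notes):
            mentions = list(assigned[j])
            if filler_pool and rng.random() < config.filler_rate:
                mentions.append(rng.choice(filler_pool))
            planted_exprs: list[tuple[str, str, object]] = []
            sentences = []
            for symptom in mentions:
                category = rng.choices(categories, weights=weights)[0]
                sentence, expr = _symptom_sentence(symptom, category, rng)
                sentences.append(sentence)
                planted_exprs.append(expr)
                truth.symptom_sequences[pid].append((timestamps[j], symptom))
            symptom_block = ("\n".join(sentences) + "\n") if sentences else ""
            cause_line = f"{cause} (caused sepsis): admitted for sepsis management.\n" if (
                use_cause and j == 0
            ) else ""
            template = rng.choice(config.template_bank)
            text = template.format(cause_line=cause_line, symptom_block=symptom_block)

            note_counter += 1
            note_id = f"N{note_counter:05d}"
            note = ClinicalNote(
                note_id=note_id,
                line_nbr=1,
                patient_id=pid,
                text=text,
                provider_id=f"D{rng.randint(1, 40):03d}",
                note_type=rng.choice(note_types),
                timestamp=timestamps[j],
            )
            notes.append(note)
            truth.temporal[(note_id, 1)] = list(planted_exprs)

            if rng.random() < config.duplicate_rate:
                dup = replace(note, line_nbr=2, text=text + "\nAddendum: labs reviewed.")
                notes.append(dup)
                truth.duplicates[(pid, note_id)] = 2
                truth.temporal[(note_id, 2)] = list(planted_exprs)

        discharge = timestamps[-1] + timedelta(hours=rng.uniform(12, 72))
        death = None
        if rng.random() < config.death_rate:
            death = timestamps[-1] + timedelta(hours=rng.uniform(1, 24))
        anchors[pid] = PatientAnchors(
            death_time=death.replace(second=0, microsecond=0) if death else None,
            discharge_time=discharge.replace(second=0, microsecond=0),
        )

    corpus = Corpus(notes=notes, name=f"synthetic-{config.seed}", anchor_times=anchors)
    corpus.validate()
    return corpus, truth


# ---------------------------------------------------------------------------
# corruption

_WORD_RE = re.compile(r"[A-Za-z]{4,}")


def corrupt(
    corpus: Corpus,
    misspelling_rate: float = 0.0,
    abbreviation_rate: float = 0.0,
    seed: int = 0,
    lexicon: TemporalLexicon | None = None,
) -> Corpus:
    """Inject misspellings and abbreviations while sparing temporal spans.

    Eligible tokens are alphabetic words of length >= 4 lying entirely
    outside every temporal-expression span of the note, so timeline tests
    remain exact on corrupted corpora.  Misspelling swaps the first
    adjacent pair of differing interior characters; abbreviation replaces
    dictionary words (pt, w/, hx, ...).  Deterministic per seed.
    """
    if not 0.0 <= misspelling_rate <= 1.0 or not 0.0 <= abbreviation_rate <= 1.0:
        raise ValidationError("corruption rates must be probabilities in [0, 1]")
    rng = random.Random(seed)
    out = []
    for note in corpus.notes:
        spans = [(e.start, e.end) for e in find_temporal_expressions(note.text, lexicon)]
        edits: list[tuple[int, int, str]] = []
        for m in _WORD_RE.finditer(note.text):
            if any(m.start() < e and m.end() > s for s, e in spans):
                continue
            word = m.group(0)
            replacement = None
            if word.lower() in _ABBREVIATIONS and rng.random() < abbreviation_rate:
                replacement = _ABBREVIATIONS[word.lower()]
            elif rng.random() < misspelling_rate:
                replacement = _swap_adjacent(word)
            if replacement is not None and replacement != word:
                edits.append((m.start(), m.end(), replacement))
        text = note.text
        for s, e, rep in reversed(edits):
            text = text[:s] + rep + text[e:]
        out.append(replace(note, text=text))
    return Corpus(notes=out, name=corpus.name, anchor_times=dict(corpus.anchor_times))


def _swap_adjacent(word: str) -> str:
    for i in range(1, len(word) - 2):
        if word[i] != word[i + 1]:
            return word[:i] + word[i + 1] + word[i] + word[i + 2 :]
    return word
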