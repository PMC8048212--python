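"""Decomposition, duration arithmetic, K-medoids and sequence building."""

import random
from datetime import datetime, timedelta

import pytest
from hypothesis import given, settings, strategies as st

from tempomine import (
    SequenceDatabase,
    TimedEntity,
    build_sequences,
    cluster_subexpressions,
    decompose,
    duration_between,
    extract_cause,
    find_temporal_expressions,
    reconstruct_corpus,
)
from tempomine.errors import ConsistencyError, ModeError, OrderingError, ParameterError
from tempomine.timeline import TemporalExpression


def _decompose(sentence):
    return decompose(sentence, find_temporal_expressions(sentence))


# ---------------------------------------------------------------------------
# decomposition


def test_duration_sentence_splits_into_symptom_and_constraint():
    d = _decompose("fever for 2 days")
    assert d.sub_expression == "fever"
    assert d.constraints == [("duration", 48.0)]


def test_sentence_without_temporal_spans_is_unchanged():
    d = _decompose("stable overnight, no events")
    assert d.sub_expression == "stable overnight, no events"
    assert d.constraints == []


def test_cue_word_excised_between_entities():
    d = _decompose("hypotension before intubation")
    assert d.sub_expression == "hypotension intubation"
    assert d.constraints == [("signal", "before")]


def test_constraints_follow_span_order():
    d = _decompose("first fever for 2 days, then hypotension")
    assert [k for k, _ in d.constraints] == ["ordinal", "duration", "signal"]
    assert d.sub_expression == "fever, hypotension"


def test_out_of_bounds_span_is_a_consistency_error():
    bad = TemporalExpression(start=10, end=20, category="explicit", surface="x")
    with pytest.raises(ConsistencyError):
        decompose("short", [bad])


def test_cause_attribution_rule():
    assert (
        extract_cause("Non-Hodgkin lymphoma (caused sepsis): fever noted.\nrest of note")
        == "Non-Hodgkin lymphoma"
    )
    assert extract_cause("Routine assessment documented.") is None


# ---------------------------------------------------------------------------
# durations


def test_masked_date_worked_example_round_trips_through_detection():
    text = "from DD-MM-YYYY 10:02 to + 2 DD-MM-YYYY 04:26"
    start, end = [e.normalized for e in find_temporal_expressions(text)]
    assert duration_between(start, end) == (42, 2)


def test_zero_and_exact_day_durations():
    t = datetime(2019, 1, 1)
    assert duration_between(t, t) == (0, 0)
    assert duration_between(t, t + timedelta(days=1)) == (24, 1)


def test_reversed_interval_rejected():
    t = datetime(2019, 1, 1)
    with pytest.raises(OrderingError):
        duration_between(t, t - timedelta(minutes=1))


@given(st.integers(0, 10_000), st.integers(0, 1439), st.integers(0, 1439))
@settings(deadline=None, derandomize=True)
def test_hour_and_day_scales_stay_consistent(day_gap_minutes, m1, m2):
    start = datetime(2019, 1, 1) + timedelta(minutes=m1)
    end = start + timedelta(minutes=day_gap_minutes + (m2 - m1))
    if end < start:
        start, end = end, start
    hours, days = duration_between(start, end)
    assert days - 1 <= hours / 24 <= days + 1


# ---------------------------------------------------------------------------
# K-medoids over sub-expressions


def test_duplicates_collapse_to_single_medoid():
    model = cluster_subexpressions(["fever", "fever", "fever"], k=1)
    assert model.medoids == {0: "fever"}
    assert model.labels == {"fever": 0}


def test_planted_paraphrase_groups_recovered():
    group_a = ["acute kidney injury", "kidney injury acute", "injury kidney"]
    group_b = ["septic shock vasopressors", "vasopressors septic shock", "shock vasopressors"]
    model = cluster_subexpressions(group_a + group_b, k=2)
    labels_a = {model.labels[s] for s in group_a}
    labels_b = {model.labels[s] for s in group_b}
    assert len(labels_a) == 1 and len(labels_b) == 1 and labels_a != labels_b


def test_swap_phase_never_worsens_objective():
    rng = random.Random(31)
    subs = [" ".join(rng.sample("abcdefghij", 3)) for _ in range(30)]
    model = cluster_subexpressions(subs, k=4)
    hist = model.objective_history
    assert all(b <= a for a, b in zip(hist, hist[1:]))
    assert model.objective == hist[-1]


def test_medoids_are_real_member_subexpressions():
    subs = ["fever chills", "rigors fever", "hypotension", "low blood pressure"]
    model = cluster_subexpressions(subs, k=2)
    for label, medoid in model.medoids.items():
        assert medoid in subs
        assert model.labels[medoid] == label


def test_k_out_of_range_rejected():
    with pytest.raises(ParameterError):
        cluster_subexpressions(["a", "b"], k=3)
    with pytest.raises(ParameterError):
        cluster_subexpressions(["a", "b"], k=0)


# ---------------------------------------------------------------------------
# sequence building


def _table_entities():
    # the canonical small example: times t1..t5, patients P1..P3, items A..E
    t = [datetime(2019, 1, d) for d in range(1, 6)]
    layout = {
        "P1": [(t[0], "A"), (t[1], "B"), (t[3], "C")],
        "P2": [(t[2], "A"), (t[2], "D"), (t[4], "E")],
        "P3": [(t[1], "A"), (t[1], "C"), (t[3], "B")],
    }
    return [
        TimedEntity(patient_id=pid, entity_label=item, anchor_time=ts)
        for pid, events in layout.items()
        for ts, item in events
    ], t


def test_same_time_symptoms_merge_into_one_itemset():
    entities, t = _table_entities()
    db = build_sequences(entities, mode="timed")
    events_p2 = dict(db.sequences["P2"])
    assert events_p2[db.times.index(t[2])] == ("A", "D")
    events_p3 = dict(db.sequences["P3"])
    assert events_p3[db.times.index(t[1])] == ("A", "C")


def test_single_entity_database():
    db = build_sequences(
        [TimedEntity(patient_id="P1", entity_label="A", anchor_time=datetime(2019, 1, 1))]
    )
    assert db.sequences == {"P1": [(0, ("A",))]}


def test_time_indices_strictly_increasing_and_itemsets_non_empty():
    entities, _ = _table_entities()
    db = build_sequences(entities)
    for events in db.sequences.values():
        indices = [t for t, _ in events]
        assert indices == sorted(set(indices))
        assert all(items for _, items in events)


def test_per_time_and_per_patient_views_pivot_round_trip():
    entities, _ = _table_entities()
    db = build_sequences(entities)
    for view in ("patient", "time"):
        frame = db.to_frame(view)
        back = SequenceDatabase.from_frame(frame, times=db.times)
        assert back == db


def test_jsonl_round_trip_preserves_sequences(tmp_path):
    entities, _ = _table_entities()
    db = build_sequences(entities)
    path = tmp_path / "seq.jsonl"
    db.to_jsonl(path)
    back = SequenceDatabase.from_jsonl(path)
    assert back.item_sequences() == db.item_sequences()


def test_timed_mode_requires_anchors():
    with pytest.raises(ModeError):
        build_sequences([TimedEntity(patient_id="P1", entity_label="A")], mode="timed")


def test_order_only_groups_by_order_key():
    entities = [
        TimedEntity(patient_id="P1", entity_label="A", order_key=0),
        TimedEntity(patient_id="P1", entity_label="B", order_key=0),
        TimedEntity(patient_id="P1", entity_label="C", order_key=1),
    ]
    db = build_sequences(entities, mode="order_only")
    assert db.sequences["P1"] == [(0, ("A", "B")), (1, ("C",))]


# ---------------------------------------------------------------------------
# corpus-level reconstruction against ground truth


def test_reconstructed_durations_match_planted_values(small_synthetic):
    config, corpus, truth = small_synthetic
    from tempomine import deduplicate

    deduped = deduplicate(corpus)
    entities, model = reconstruct_corpus(
        deduped, k_entities=len(config.symptom_vocabulary), seed=0
    )
    # medoids are exactly the planted symptom phrases
    assert set(model.medoids.values()) <= set(config.symptom_vocabulary)
    # (entity, duration) pairs equal the planted explicit durations of the
    # surviving (maximal line_nbr) version of each note
    planted_hours = sorted(
        (key[0], norm)
        for key, exprs in truth.temporal.items()
        if key[1] == max(l for (nid, l) in truth.temporal if nid == key[0])
        for _, _, norm in exprs
        if norm is not None
    )
    got_hours = sorted(
        (e.source_note, e.duration_hours) for e in entities if e.duration_hours is not None
    )
    assert got_hours == planted_hours


def test_cause_propagates_to_entities(small_synthetic):
    config, corpus, truth = small_synthetic
    entities, _ = reconstruct_corpus(corpus, k_entities=5, seed=0)
    by_patient = {}
    for e in entities:
        if e.cause is not None:
            by_patient.setdefault(e.patient_id, set()).add(e.cause)
    for pid, cause in truth.causes.items():
        if pid in by_patient:
            assert by_patient[pid] == {cause}
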