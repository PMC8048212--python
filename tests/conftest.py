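from datetime import datetime

import pytest

from tempomine import Corpus, ClinicalNote, GeneratorConfig, PatientAnchors, generate


@pytest.fixture(scope="session")
def small_synthetic():
    """A small seeded synthetic corpus shared by read-only tests."""
    config = GeneratorConfig(n_patients=6, seed=7)
    corpus, truth = generate(config)
    return config, corpus, truth


@pytest.fixture
def tiny_corpus():
    """Three hand-written notes for two patients, with anchors."""
    t = datetime(2019, 3, 1, 10, 0)
    notes = [
        ClinicalNote("N1", 1, "PA", "fever for 2 days.", timestamp=t),
        ClinicalNote("N2", 1, "PA", "hypotension before intubation.", timestamp=t.replace(hour=14)),
        ClinicalNote("N3", 1, "PB", "first episode of sepsis.", timestamp=t.replace(day=2)),
    ]
    anchors = {
        "PA": PatientAnchors(discharge_time=datetime(2019, 3, 4, 10, 0)),
        "PB": PatientAnchors(
            discharge_time=datetime(2019, 3, 5, 10, 0), death_time=datetime(2019, 3, 5, 12, 0)
        ),
    }
    return Corpus(notes=notes, name="tiny", anchor_times=anchors)
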