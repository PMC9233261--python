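import numpy as np
import pytest

from sensiterm.corpus_io import Note
from sensiterm.lexicon import LexiconEntry
from sensiterm.synthetic_corpus import default_config, generate_corpus


def make_note(note_id="N1", text="patient seen today .", note_type="apn",
              age_years=5, **kw):
    defaults = dict(patient_id="P1", provider_type="attending",
                    setting="ambulatory", specialty="primary_care")
    defaults.update(kw)
    return Note(note_id=note_id, text=text, note_type=note_type,
                age_years=age_years, **defaults)


@pytest.fixture
def three_notes():
    return [
        make_note("N1", "Patient denies ETOH use.", "hp", 15,
                  setting="inpatient", specialty="hospital_medicine"),
        make_note("N2", "anxiety screening negative today .", "apn", 8),
        make_note("N3", "routine visit , no concerns .", "epn", 2,
                  setting="emergency", specialty="emergency_medicine"),
    ]


@pytest.fixture
def tiny_lexicon():
    return [
        LexiconEntry("etoh", "substance_use", "abbreviation", "alcohol"),
        LexiconEntry("anxiety", "mental_health", "seed", "anxiety"),
        LexiconEntry("suicidal", "mental_health", "seed", "suicidal"),
        LexiconEntry("suicidal ideation", "mental_health", "related",
                     "suicidal"),
    ]


@pytest.fixture(scope="session")
def small_corpus():
    """~1100-note default-condition corpus shared across tests."""
    cfg = default_config(n_patients=300, rng_seed=42)
    notes, truth = generate_corpus(cfg)
    return cfg, notes, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
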