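import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from mig_rwe import knowledge as kn
from mig_rwe.corpus_model import CodedEntry, Corpus, Encounter

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def lexicon():
    return kn.default_lexicon()


@pytest.fixture(scope="session")
def code_map():
    return kn.default_code_map()


@pytest.fixture(scope="session")
def assoc_table():
    return kn.default_association_table()


def make_encounter(encounter_id="E1", patient_id="P1", physician_id="D1",
                   date=dt.date(2011, 3, 1), note_text="", problem_list=(),
                   medication_list=(), claims=()):
    return Encounter(
        patient_id=patient_id,
        encounter_id=encounter_id,
        physician_id=physician_id,
        date=date,
        problem_list=[CodedEntry(*e) for e in problem_list],
        medication_list=[CodedEntry(*e) for e in medication_list],
        claims=[CodedEntry(*e) for e in claims],
        note_text=note_text,
    )


def make_corpus(*encounters):
    return Corpus(list(encounters))


@pytest.fixture
def tiny_corpus():
    return make_corpus(
        make_encounter("E1", "P1", note_text="Pt reports severe HEADACHE."),
        make_encounter("E2", "P2", date=dt.date(2011, 3, 2),
                       note_text="Annual wellness visit, no complaints."),
        make_encounter("E3", "P1", date=dt.date(2011, 4, 1),
                       note_text="Continue sumatriptan as needed.",
                       medication_list=[("DRUG", "SUMATRIPTAN")]),
    )
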