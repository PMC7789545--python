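import datetime as dt

import pytest

from rwegm import textprep


@pytest.fixture
def make_record():
    """Factory for annotated sentence records."""

    def _make(text, patient="P1", note="N1", date="2018-01-01"):
        rec = textprep.SentenceRecord(
            patient_id=patient, note_id=note,
            date=textprep.parse_date(date), raw_text=text,
        )
        return textprep.annotate(rec)

    return _make


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-patient synthetic cohort shared across tests (seeded)."""
    from rwegm import synthetic

    spec = synthetic.CohortSpec(n_patients=120, seed=5)
    return synthetic.generate_cohort(spec)


@pytest.fixture(scope="session")
def annotated_cohort(small_cohort):
    """Extracted + annotated + deduplicated sentences with gold topics."""
    gold = small_cohort.gold_labels.set_index(["patient_id", "note_id"])["topic"]
    ann = [textprep.annotate(r)
           for r in textprep.extract_target_sentences(small_cohort.sentences)]
    dedup = textprep.deduplicate_per_patient(ann)
    labels = [gold.loc[(r.patient_id, r.note_id)] for r in dedup]
    return dedup, labels
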