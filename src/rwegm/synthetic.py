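"""Synthetic labeled cohorts for the note-mining pipeline.

Real clinical notes cannot be shared, so this module generates cohorts with
the statistical structure the pipeline assumes and a full gold standard for
every stage: per-sentence topic labels, reference genetic-report tables,
medication sources, injected documentation discrepancies, and per-patient
therapy status.

Each synthetic patient follows a templated medical journey
(Evaluation/Information first, then Order, optionally Insurance, then
repeated result mentions), with duplicated sentences across notes, field
level missingness of variant details at configurable rates, and a
configurable rate of injected gene-switch discrepancies.  Topic templates use
disjoint slot vocabularies so that indicator words are recoverable by PMI and
feature importance by construction.  Clinical realism of the language is
secondary to the statistical structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date as Date
from datetime import timedelta
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .textprep import SentenceRecord

TARGET_GENES = ("BRCA1", "BRCA2")

# ---------------------------------------------------------------------------
# sentence templates ({G} = target gene slot); content words are disjoint
# across topics so that PMI / feature importance can recover them

EVALUATION_TEMPLATES = [
    "Estimated risk of {G} mutation given strong family history.",
    "Patient has a family history of breast cancer and elevated {G} carrier risk.",
    "Hereditary cancer risk assessment for {G} was performed.",
    "Genetic counseling addressed the benefit of {G} testing for this family.",
]
INFORMATION_TEMPLATES = [
    "Provided information about the {G} testing guideline.",
    "Reviewed gene panel education materials covering {G}.",
    "General information on the {G} repair pathway was provided.",
    "Gave the patient an education brochure about {G}.",
]
ORDER_TEMPLATES = [
    "{G} genetic test was ordered today.",
    "Awaiting results of the {G} test, specimen sent to the lab.",
    "{G} test order placed, results pending.",
]
INSURANCE_TEMPLATES = [
    "Insurance coverage for {G} testing was requested.",
    "Prior authorization for {G} testing under review by insurance.",
    "Insurance denial for {G} testing is being appealed, copay discussed.",
]
PARP_DISCUSSION_TEMPLATE = (
    "Discussed PARP inhibitor {DRUG} as a targeted option related to {G}."
)
CURRENT_MED_TEMPLATE = "Current Medications: {DRUG} 300 mg twice daily."
PARP_DRUGS = ("olaparib", "rucaparib", "niraparib")

HGVS_SNVS = ("c.7759C > T", "p.Arg149Trp", "c.5096G > A", "p.Ser34Phe")
HGVS_INDELS = ("c.68_69delAG", "c.5266dupC")
CNV_TERMS = ("amplification", "deletion")
REARR_TERMS = ("rearrangement", "truncation")
CLASS_PHRASES = (
    "consistent with a splice site change",
    "consistent with a missense mutation",
    "consistent with a nonsense mutation",
)
SOURCE_PHRASES = ("on germline analysis", "on somatic analysis")
RESULT_LEADS = ("Genetic testing showed", "Repeat genetic testing showed",
                "Outside records again showed")


def _result_sentence(
    status: str,
    gene: str,
    hgvs: str = "",
    term: str = "",
    pathogenic_wording: bool = False,
    classification_phrase: str = "",
    source_phrase: str = "",
    vus_style: str = "unknown_significance",
    lead: str = "Genetic testing showed",
) -> str:
    """Compose a result sentence embedding the requested data elements."""
    mid = f" {hgvs}" if hgvs else (f" {term}" if term else "")
    if status == "Positive":
        core = f"{lead} {gene}{mid} positive result"
        if pathogenic_wording:
            core += ", a pathogenic alteration"
    elif status == "Negative":
        core = f"{lead} {gene}{mid} negative result"
    elif status == "VUS":
        if vus_style == "vus":
            core = f"{lead} {gene}{mid} VUS reported"
        elif mid:
            core = f"{lead} {gene}{mid}, a variant of unknown significance"
        else:
            core = f"{lead} {gene} variant of unknown significance"
    else:
        raise ValueError(f"unknown status {status!r}")
    if classification_phrase:
        core += f", {classification_phrase}"
    if source_phrase:
        core += f" {source_phrase}"
    return core + "."


# ---------------------------------------------------------------------------
# cohort specification


@dataclass
class CohortSpec:
    """Generator parameters; defaults mirror the study conditions.

    ``mutation_prevalence`` reflects a 196-patient cohort with 12 mutated and
    24 VUS reference reports; ``capture`` gives the probability that a
    patient's reference result is also documented in notes (0.75 positive,
    0.208 VUS); ``field_missingness`` holds per-field dropout probabilities
    for variant details in result sentences (complements of the audited
    completeness rates); ``duplication_rate`` mirrors a corpus where roughly
    42% of sentence instances are within-patient duplicates.
    """

    n_patients: int = 196
    seed: int = 7
    mutation_prevalence: dict = field(default_factory=lambda: {
        "Mutated": 12 / 196, "VUS": 24 / 196, "Negative": 160 / 196})
    capture: dict = field(default_factory=lambda: {
        "Mutated": 0.75, "VUS": 0.208, "Negative": 0.6})
    duplication_rate: float = 0.42
    discrepancy_rate: float = 0.05
    field_missingness: dict = field(default_factory=lambda: {
        "hgvs": 0.75, "variant_type": 0.5, "pathogenicity": 0.562,
        "classification": 0.937, "source": 0.736})
    therapy_discussion: dict = field(default_factory=lambda: {
        "Mutated": 0.9, "VUS": 0.6, "Negative": 0.45})
    therapy_prescription: dict = field(default_factory=lambda: {
        "Mutated": 0.6, "VUS": 0.15, "Negative": 0.04})
    p_second_evaluation: float = 0.2
    p_second_information: float = 0.4
    p_information_first: float = 0.4
    p_insurance: float = 0.3
    max_result_mentions: int = 3
    start_date: Date = Date(2017, 1, 1)

    def validate(self) -> None:
        probs = (
            list(self.mutation_prevalence.values())
            + list(self.capture.values())
            + [self.duplication_rate, self.discrepancy_rate]
            + list(self.field_missingness.values())
            + list(self.therapy_discussion.values())
            + list(self.therapy_prescription.values())
            + [self.p_second_evaluation, self.p_second_information,
               self.p_information_first, self.p_insurance]
        )
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if abs(sum(self.mutation_prevalence.values()) - 1.0) > 1e-9:
            raise ValueError("mutation_prevalence must sum to 1")
        if self.n_patients < 1 or self.max_result_mentions < 1:
            raise ValueError("inconsistent cohort spec")


@dataclass
class Cohort:
    """Generated cohort with full gold standard."""

    sentences: list[SentenceRecord]
    gold_labels: pd.DataFrame          # patient_id, note_id, topic
    reference_reports: pd.DataFrame    # patient_id, gene, status, variant, report_date
    medications: pd.DataFrame          # patient_id, drug, date
    cdm_lines: list[tuple[str, str]]   # (patient_id, line)
    gold_discrepancies: pd.DataFrame   # patient_id, gene_original, gene_switched, date
    gold_therapy: pd.DataFrame         # patient_id, mutation_status, discussion, prescription

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "notes.jsonl", "w") as fh:
            for s in self.sentences:
                fh.write(json.dumps({
                    "patient_id": s.patient_id, "note_id": s.note_id,
                    "date": s.date.isoformat() if s.date else "",
                    "text": s.raw_text,
                }) + "\n")
        self.gold_labels.to_csv(out / "gold_labels.csv", index=False)
        self.reference_reports.to_csv(out / "reports.csv", index=False)
        self.medications.to_csv(out / "meds.csv", index=False)
        self.gold_discrepancies.to_csv(out / "gold_discrepancies.csv", index=False)
        self.gold_therapy.to_csv(out / "gold_therapy.csv", index=False)
        with open(out / "cdm.txt", "w") as fh:
            for pid, line in self.cdm_lines:
                fh.write(f"{pid}\t{line}\n")


def generate_cohort(spec: Optional[CohortSpec] = None) -> Cohort:
    """Generate a cohort; byte-identical output for identical seeds."""
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    p_hgvs = 1.0 - spec.field_missingness["hgvs"]
    p_type = 1.0 - spec.field_missingness["variant_type"]
    p_term = max(0.0, (p_type - p_hgvs) / (1.0 - p_hgvs)) if p_hgvs < 1 else 0.0
    p_path = 1.0 - spec.field_missingness["pathogenicity"]
    p_class = 1.0 - spec.field_missingness["classification"]
    p_source = 1.0 - spec.field_missingness["source"]

    sentences: list[SentenceRecord] = []
    gold_rows, report_rows, med_rows, disc_rows, ther_rows = [], [], [], [], []
    cdm_lines: list[tuple[str, str]] = []

    statuses = list(spec.mutation_prevalence)
    status_p = np.array([spec.mutation_prevalence[s] for s in statuses])

    for i in range(spec.n_patients):
        pid = f"P{i + 1:04d}"
        mstat = statuses[int(rng.choice(len(statuses), p=status_p))]
        gene = TARGET_GENES[int(rng.integers(2))]
        day = spec.start_date + timedelta(days=int(rng.integers(0, 365)))
        note_seq = 0
        timeline: list[tuple[Date, str, str]] = []  # (date, text, topic)

        def next_date(d: Date) -> Date:
            return d + timedelta(days=int(rng.integers(7, 61)))

        def pick(templates) -> str:
            return templates[int(rng.integers(len(templates)))].format(
                G=gene, DRUG=PARP_DRUGS[int(rng.integers(len(PARP_DRUGS)))])

        # Evaluation / Information block (either may come first)
        n_eval = 1 + int(rng.random() < spec.p_second_evaluation)
        n_info = 1 + int(rng.random() < spec.p_second_information)
        discussion = rng.random() < spec.therapy_discussion[mstat]
        block: list[tuple[str, str]] = []

        def pick_distinct(templates, k):
            # without replacement so a patient's sentences stay lexically distinct
            idx = rng.choice(len(templates), size=min(k, len(templates)), replace=False)
            return [templates[int(i)].format(
                G=gene, DRUG=PARP_DRUGS[int(rng.integers(len(PARP_DRUGS)))])
                for i in idx]

        eval_sents = [(t, "Evaluation") for t in pick_distinct(EVALUATION_TEMPLATES, n_eval)]
        info_sents = [(t, "Information") for t in pick_distinct(INFORMATION_TEMPLATES, n_info)]
        if discussion:
            info_sents.append(
                (PARP_DISCUSSION_TEMPLATE.format(
                    G=gene, DRUG=PARP_DRUGS[int(rng.integers(len(PARP_DRUGS)))]),
                 "Information"))
        if rng.random() < spec.p_information_first:
            block = info_sents + eval_sents
        else:
            block = eval_sents + info_sents
        for text, topic in block:
            timeline.append((day, text, topic))
            day = next_date(day)

        # Order, optional Insurance
        timeline.append((day, pick(ORDER_TEMPLATES), "Order"))
        day = next_date(day)
        if rng.random() < spec.p_insurance:
            timeline.append((day, pick(INSURANCE_TEMPLATES), "Insurance"))
            day = next_date(day)

        # reference report precedes result documentation
        variant = HGVS_SNVS[int(rng.integers(len(HGVS_SNVS)))] if mstat != "Negative" else ""
        report_rows.append({
            "patient_id": pid, "gene": gene,
            "status": {"Mutated": "positive", "VUS": "vus", "Negative": "negative"}[mstat],
            "variant": variant.replace(" ", ""), "report_date": day.isoformat(),
        })
        day = next_date(day)

        # result mentions (only when the result is captured in notes)
        documented = rng.random() < spec.capture[mstat]
        topic = {"Mutated": "Positive", "VUS": "VUS", "Negative": "Negative"}[mstat]
        if documented:
            n_mentions = 1 + int(rng.integers(spec.max_result_mentions))
            for mention_j in range(n_mentions):
                hgvs = term = class_phrase = source_phrase = ""
                pathogenic_wording = False
                if topic in ("Positive", "VUS"):
                    if rng.random() < p_hgvs:
                        pool = HGVS_SNVS + HGVS_INDELS
                        hgvs = pool[int(rng.integers(len(pool)))]
                    elif rng.random() < p_term:
                        pool = CNV_TERMS + REARR_TERMS
                        term = pool[int(rng.integers(len(pool)))]
                    if topic == "Positive" and rng.random() < p_path:
                        pathogenic_wording = True
                    if rng.random() < p_class:
                        class_phrase = CLASS_PHRASES[int(rng.integers(len(CLASS_PHRASES)))]
                if rng.random() < p_source:
                    source_phrase = SOURCE_PHRASES[int(rng.integers(len(SOURCE_PHRASES)))]
                vus_style = ("vus" if topic == "VUS" and rng.random() < 0.5
                             else "unknown_significance")
                text = _result_sentence(topic, gene, hgvs, term,
                                        pathogenic_wording, class_phrase,
                                        source_phrase, vus_style,
                                        lead=RESULT_LEADS[mention_j % len(RESULT_LEADS)])
                timeline.append((day, text, topic))
                day = next_date(day)

            # injected gene-switch discrepancy (same status, the other gene)
            if topic in ("Positive", "VUS") and rng.random() < spec.discrepancy_rate:
                other = TARGET_GENES[1 - TARGET_GENES.index(gene)]
                text = _result_sentence(topic, other)
                timeline.append((day, text, topic))
                disc_rows.append({
                    "patient_id": pid, "gene_original": gene,
                    "gene_switched": other, "date": day.isoformat(),
                })
                day = next_date(day)

        # prescription sources
        prescription = discussion and rng.random() < spec.therapy_prescription[mstat]
        if prescription:
            drug = PARP_DRUGS[int(rng.integers(len(PARP_DRUGS)))]
            source = int(rng.integers(3))
            if source == 0:
                med_rows.append({"patient_id": pid, "drug": drug.capitalize(),
                                 "date": day.isoformat()})
            elif source == 1:
                cdm_lines.append((pid, f"Trial drug administration: {drug} per protocol"))
            else:
                timeline.append((day, CURRENT_MED_TEMPLATE.format(DRUG=drug), ""))
                day = next_date(day)
        ther_rows.append({"patient_id": pid, "mutation_status": mstat,
                          "discussion": discussion, "prescription": prescription})

        # materialize notes, then duplicate some sentences into later notes
        dated: list[tuple[Date, str, str]] = list(timeline)
        for d, text, topic in timeline:
            if topic and rng.random() < spec.duplication_rate:
                dup_day = d + timedelta(days=int(rng.integers(30, 181)))
                dated.append((dup_day, text, topic))
        dated.sort(key=lambda t: t[0])
        for d, text, topic in dated:
            note_seq += 1
            nid = f"{pid}-N{note_seq:03d}"
            sentences.append(SentenceRecord(
                patient_id=pid, note_id=nid, date=d, raw_text=text))
            if topic:
                gold_rows.append({"patient_id": pid, "note_id": nid, "topic": topic})

    return Cohort(
        sentences=sentences,
        gold_labels=pd.DataFrame(gold_rows, columns=["patient_id", "note_id", "topic"]),
        reference_reports=pd.DataFrame(
            report_rows, columns=["patient_id", "gene", "status", "variant", "report_date"]),
        medications=pd.DataFrame(med_rows, columns=["patient_id", "drug", "date"]),
        cdm_lines=cdm_lines,
        gold_discrepancies=pd.DataFrame(
            disc_rows, columns=["patient_id", "gene_original", "gene_switched", "date"]),
        gold_therapy=pd.DataFrame(
            ther_rows, columns=["patient_id", "mutation_status", "discussion", "prescription"]),
    )


# ---------------------------------------------------------------------------
# worked-example fixture reproducing the printed audit fractions


@dataclass
class Table1Fixture:
    sentences: list[SentenceRecord]
    reference_reports: pd.DataFrame


def table1_fixture() -> Table1Fixture:
    """Fixed small cohort engineered to the documented audit fractions.

    91 result sentences (11 Positive + 5 VUS + 75 Negative), of which the 16
    Positive/VUS records carry: a variant-type cue in 8 (4 HGVS strings, 2
    copy-number terms, 2 rearrangement terms), explicit pathogenicity wording
    in 7 (5 VUS + 2 "pathogenic"), a classification keyword in 1 (splice
    site) and an HGVS string in 4; 24 of all 91 carry germline/somatic
    wording.  The reference table holds 12 positive patients (9 documented in
    notes) and 24 VUS patients (5 documented).
    """
    sentences: list[SentenceRecord] = []
    ref_rows = []
    base = Date(2018, 3, 1)
    counter = [0]

    def add(pid: str, text: str) -> None:
        counter[0] += 1
        sentences.append(SentenceRecord(
            patient_id=pid, note_id=f"{pid}-N{counter[0]:03d}",
            date=base + timedelta(days=counter[0]), raw_text=text))

    def gene_for(i: int) -> str:
        return TARGET_GENES[i % 2]

    # reference: 12 positive patients, 24 VUS patients
    for i in range(12):
        ref_rows.append({"patient_id": f"REFP{i + 1:02d}", "gene": gene_for(i),
                         "status": "positive", "variant": "",
                         "report_date": (base - timedelta(days=30)).isoformat()})
    for i in range(24):
        ref_rows.append({"patient_id": f"REFV{i + 1:02d}", "gene": gene_for(i),
                         "status": "vus", "variant": "",
                         "report_date": (base - timedelta(days=30)).isoformat()})

    # 11 Positive sentences: 9 in matched reference patients, 2 extra
    pos_specs = [
        {"hgvs": "c.7759C > T"},
        {"hgvs": "p.Arg149Trp"},
        {"hgvs": "c.68_69delAG"},
        {"term": "amplification"},
        {"term": "amplification"},
        {"term": "rearrangement"},
        {"term": "rearrangement"},
        {"pathogenic_wording": True},
        {"pathogenic_wording": True},
        {"source_phrase": "on germline analysis"},
        {"classification_phrase": "consistent with a splice site change"},
    ]
    for i, kw in enumerate(pos_specs):
        pid = f"REFP{i + 1:02d}" if i < 9 else f"EXTRA{i - 8:02d}"
        add(pid, _result_sentence("Positive", gene_for(i), **kw))

    # 5 VUS sentences, all in matched reference patients
    vus_specs = [
        {"hgvs": "c.5096G > A"},
        {"source_phrase": "on somatic analysis"},
        {}, {}, {},
    ]
    for i, kw in enumerate(vus_specs):
        add(f"REFV{i + 1:02d}", _result_sentence("VUS", gene_for(i), **kw))

    # 75 Negative sentences; 22 carry source wording (24 sources in total)
    for i in range(75):
        kw = {"source_phrase": SOURCE_PHRASES[i % 2]} if i < 22 else {}
        add(f"NEG{i + 1:03d}", _result_sentence("Negative", gene_for(i), **kw))

    return Table1Fixture(
        sentences=sentences,
        reference_reports=pd.DataFrame(
            ref_rows, columns=["patient_id", "gene", "status", "variant", "report_date"]),
    )
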