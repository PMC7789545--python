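"""Clinical-genomics data model, completeness audit, discrepancy detection and
topic timelines.

The data model mirrors an internal curation schema for genetic test results
(one row per extracted result assertion).  The audit measures, field by field,
how completely result-bearing sentences in clinical notes populate the model;
``capture_rate`` compares note-derived records against reference report
tables; ``detect_discrepancies`` flags contradictory documentation within a
patient timeline; ``topic_rank_matrix`` summarizes when in the medical journey
each topic occurs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from datetime import date as Date
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Optional, Sequence

import pandas as pd

RESULT_TOPICS = ("Positive", "Negative", "VUS")
ALL_TOPICS = ("Information", "Evaluation", "Insurance", "Order", "Negative", "Positive", "VUS")

ALLOWED_VARIANT_TYPES = ("SNP", "INDEL", "CNV", "Rearrangement")
ALLOWED_SOURCES = ("somatic", "germline")
ALLOWED_PATHOGENICITY = ("actionable", "pathogenic", "VUS")
ALLOWED_CLASSIFICATIONS = (
    "Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins",
    "Missense_Mutation", "Nonsense_Mutation", "Silent", "Splice_Site",
    "Translation_Start_Site", "Nonstop_Mutation", "3'UTR", "3'Flank", "5'UTR",
    "5'Flank", "IGR", "Intron", "RNA", "Targeted_Region",
    "De_novo_Start_InFrame", "De_novo_Start_OutOfFrame",
)

# the five audited data elements
AUDIT_FIELDS = (
    "Variant_Type",
    "Variant_Source",
    "Variant_Pathogenicity",
    "Variant_Classification",
    "HGVS_Short",
)


@dataclass
class VariantRecord:
    """One curated genetic-result row (column names follow the data model)."""

    Hugo_Symbol: str = ""
    Ensemble_Gene_ID: str = ""
    Transcript_ID: str = ""
    De_sample_ID: str = ""
    Pathogeneity_Report_Date: str = ""
    Variant_Type: str = ""
    Variant_Source: str = ""
    Variant_Pathogenicity: str = ""
    Variant_Classification: str = ""
    HGVS_Short: str = ""
    NCBI_Build: str = ""
    Chromosome: str = ""
    Start_Position: str = ""
    End_Position: str = ""
    Strand: str = ""
    Variant_Allele_Freq: str = ""
    BP_Coverage: str = ""
    Variant_Pathogenicity_Updated: str = ""
    Pathogeneity_Update_Date: str = ""
    # provenance (not part of the curation schema itself)
    patient_id: str = ""
    note_id: str = ""
    date: Optional[Date] = None
    topic: str = ""          # Positive | Negative | VUS
    is_negative: bool = False  # wildtype assertion flag

    def __post_init__(self) -> None:
        for name, allowed in (
            ("Variant_Type", ALLOWED_VARIANT_TYPES),
            ("Variant_Source", ALLOWED_SOURCES),
            ("Variant_Pathogenicity", ALLOWED_PATHOGENICITY),
            ("Variant_Classification", ALLOWED_CLASSIFICATIONS),
        ):
            val = getattr(self, name)
            if val and val not in allowed:
                raise ValueError(f"{name}={val!r} not in allowed values")


MODEL_COLUMNS = [f.name for f in dc_fields(VariantRecord) if f.name not in
                 ("patient_id", "note_id", "date", "topic", "is_negative")]


def records_to_frame(records: Sequence[VariantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in MODEL_COLUMNS}
        row.update(
            patient_id=r.patient_id, note_id=r.note_id,
            date=r.date.isoformat() if r.date else "", topic=r.topic,
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=MODEL_COLUMNS + ["patient_id", "note_id", "date", "topic"])


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round half-up, the convention of the printed audit tables (43.75 -> 43.8)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FieldCompleteness:
    field: str
    numerator: int
    denominator: int

    @property
    def percent(self) -> Optional[float]:
        if self.denominator == 0:
            return None
        return round_half_up(100.0 * self.numerator / self.denominator, 1)


CompletenessReport = dict[str, FieldCompleteness]


def completeness(
    records: Sequence[VariantRecord],
    fields: Iterable[str] = AUDIT_FIELDS,
) -> CompletenessReport:
    """Field-level completeness of result records.

    Scoping: Variant_Source is expected for every result record (Positive,
    VUS and Negative sentences — the testing panel type implies it), while
    the other audited fields are expected only for Positive and VUS records.
    Percentages are rounded half-up to one decimal.
    """
    report: CompletenessReport = {}
    pos_vus = [r for r in records if r.topic in ("Positive", "VUS")]
    all_results = [r for r in records if r.topic in RESULT_TOPICS]
    for f in fields:
        scope = all_results if f == "Variant_Source" else pos_vus
        num = sum(1 for r in scope if getattr(r, f))
        report[f] = FieldCompleteness(field=f, numerator=num, denominator=len(scope))
    return report


@dataclass(frozen=True)
class CaptureRate:
    n_matched: int
    n_reference: int

    @property
    def fraction(self) -> float:
        return self.n_matched / self.n_reference if self.n_reference else 0.0

    @property
    def percent(self) -> float:
        return round_half_up(100.0 * self.fraction, 1)


_STATUS_TOPIC = {"positive": "Positive", "pathogenic": "Positive", "mutated": "Positive",
                 "vus": "VUS", "negative": "Negative", "wildtype": "Negative"}


def capture_rate(
    reference: pd.DataFrame,
    extracted: Sequence[VariantRecord],
    status: str,
    strict: bool = False,
) -> CaptureRate:
    """Fraction of reference-report patients of a given mutation status whose
    result is also documented in notes (same gene + compatible topic).

    ``reference`` needs columns patient_id, gene, status.  With
    ``strict=True`` the extracted HGVS_Short must additionally match the
    reference ``variant`` column.
    """
    want_topic = _STATUS_TOPIC[status.lower()]
    ref = reference[reference["status"].str.lower().map(
        lambda s: _STATUS_TOPIC.get(s) == want_topic)]
    by_patient: dict[str, list[VariantRecord]] = {}
    for r in extracted:
        by_patient.setdefault(r.patient_id, []).append(r)
    matched = 0
    for _, row in ref.iterrows():
        hits = [
            r for r in by_patient.get(str(row["patient_id"]), [])
            if r.topic == want_topic and r.Hugo_Symbol == str(row["gene"]).upper()
        ]
        if strict:
            want_var = str(row.get("variant", "") or "")
            hits = [r for r in hits if want_var and r.HGVS_Short == want_var]
        if hits:
            matched += 1
    return CaptureRate(n_matched=matched, n_reference=len(ref))


# ---------------------------------------------------------------------------
# discrepancy detection


@dataclass(frozen=True)
class DiscrepancyFlag:
    kind: str  # "gene_switch" | "status_flip"
    patient_id: str
    detail: tuple[str, str]            # (gene_a, gene_b) or (status_a, status_b)
    provenance: tuple[tuple, tuple]    # two (date, note_id, gene, status) tuples


def detect_discrepancies(records: Sequence[VariantRecord]) -> list[DiscrepancyFlag]:
    """Flag contradictory result documentation within each patient timeline.

    gene_switch: the same positivity status asserted for two different target
    genes on different dates (e.g. first documented positive in BRCA2, later
    revised to BRCA1).  status_flip: pathogenic vs wildtype assertions for the
    same gene.  Flags are deduplicated per (patient, kind, detail) and are the
    same whichever direction the timeline is scanned.
    """
    by_patient: dict[str, list[VariantRecord]] = {}
    for r in records:
        if r.topic in RESULT_TOPICS:
            by_patient.setdefault(r.patient_id, []).append(r)
    flags: dict[tuple, DiscrepancyFlag] = {}
    for pid, recs in by_patient.items():
        recs = sorted(recs, key=lambda r: (r.date or Date.min, r.note_id))
        for i, a in enumerate(recs):
            for b in recs[i + 1:]:
                prov = (
                    (a.date, a.note_id, a.Hugo_Symbol, a.topic),
                    (b.date, b.note_id, b.Hugo_Symbol, b.topic),
                )
                if (
                    a.topic == b.topic
                    and a.topic in ("Positive", "VUS")
                    and a.Hugo_Symbol != b.Hugo_Symbol
                    and a.date != b.date
                ):
                    key = (pid, "gene_switch", a.topic,
                           tuple(sorted((a.Hugo_Symbol, b.Hugo_Symbol))))
                    flags.setdefault(key, DiscrepancyFlag(
                        "gene_switch", pid, (a.Hugo_Symbol, b.Hugo_Symbol), prov))
                if (
                    a.Hugo_Symbol == b.Hugo_Symbol
                    and {a.topic, b.topic} == {"Positive", "Negative"}
                ):
                    key = (pid, "status_flip", a.Hugo_Symbol)
                    flags.setdefault(key, DiscrepancyFlag(
                        "status_flip", pid, (a.topic, b.topic), prov))
    return [flags[k] for k in sorted(flags, key=str)]


# ---------------------------------------------------------------------------
# temporal topic-rank matrix


def topic_rank_matrix(
    timelines: dict[str, Sequence[tuple[Date, str, str]]],
    max_rank: Optional[int] = None,
    topics: Sequence[str] = ALL_TOPICS,
) -> pd.DataFrame:
    """Topic x occurrence-rank matrix of row-normalized percentages.

    ``timelines`` maps patient_id to (date, note_id, topic) encounters.  Every
    encounter counts (repeated result mentions included); within a patient,
    encounters are ranked by date with note_id breaking same-date ties.  Cell
    (t, k) is the percentage of topic-t mentions that happened at rank k;
    each non-empty row sums to 100.
    """
    counts: dict[str, dict[int, int]] = {t: {} for t in topics}
    max_seen = 0
    for _pid, events in timelines.items():
        ordered = sorted(events, key=lambda e: (e[0], e[1]))
        for rank, (_d, _nid, topic) in enumerate(ordered, start=1):
            if max_rank is not None and rank > max_rank:
                break
            if topic in counts:
                counts[topic][rank] = counts[topic].get(rank, 0) + 1
                max_seen = max(max_seen, rank)
    ranks = list(range(1, (max_rank or max_seen) + 1))
    mat = pd.DataFrame(0.0, index=list(topics), columns=ranks)
    for t in topics:
        row_total = sum(counts[t].values())
        if row_total == 0:
            continue
        for k, c in counts[t].items():
            mat.loc[t, k] = 100.0 * c / row_total
    return mat
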