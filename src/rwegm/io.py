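"""Reading and writing the pipeline's delimited/JSONL interchange formats."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .corpus_stats import PmiEntry, SfIpfScore
from .quality import VariantRecord, records_to_frame
from .textprep import SentenceRecord, parse_date


def read_sentences(path) -> list[SentenceRecord]:
    """Read sentence records from JSONL or CSV.

    Expected columns/keys: patient_id, note_id, date (ISO-8601 or
    mm/dd/yyyy), text.  Unparseable dates become None (downstream extraction
    rejects those records with a warning).
    """
    path = Path(path)
    records = []
    if path.suffix.lower() in (".jsonl", ".json", ".ndjson"):
        with open(path) as fh:
            rows: Iterable[dict] = (json.loads(line) for line in fh if line.strip())
            records = [_row_to_record(r) for r in rows]
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        records = [_row_to_record(r) for r in df.to_dict("records")]
    return records


def _row_to_record(row: dict) -> SentenceRecord:
    return SentenceRecord(
        patient_id=str(row["patient_id"]),
        note_id=str(row.get("note_id", "")),
        date=parse_date(row.get("date")),
        raw_text=str(row.get("text", row.get("raw_text", ""))),
    )


def write_sentences(records: Sequence[SentenceRecord], path) -> None:
    """Write enriched sentence records as JSONL."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(json.dumps({
                "patient_id": r.patient_id,
                "note_id": r.note_id,
                "date": r.date.isoformat() if r.date else "",
                "text": r.raw_text,
                "masked_text": r.masked_text,
                "tokens": r.tokens,
                "gene_mentions": [
                    {"symbol": g.symbol, "span": list(g.span), "is_target": g.is_target}
                    for g in r.gene_mentions],
                "variant_mentions": [
                    {"raw": v.raw, "syntax_kind": v.syntax_kind, "span": list(v.span)}
                    for v in r.variant_mentions],
            }) + "\n")


def write_scores(scores: Sequence[SfIpfScore], path) -> None:
    pd.DataFrame([{
        "sentence_key": s.sentence_key, "text": s.text, "sf": s.sf,
        "ipf": s.ipf, "score": s.score, "n_patients": s.n_patients_with,
        "count": s.count,
    } for s in scores]).to_csv(path, index=False)


def write_pmi(entries: Sequence[PmiEntry], path) -> None:
    pd.DataFrame([{
        "word": e.word, "topic": e.topic, "pmi": e.pmi,
        "count_wt": e.count_wt, "count_w": e.count_w, "count_t": e.count_t,
    } for e in entries]).to_csv(path, index=False)


def write_variant_records(records: Sequence[VariantRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_labels(path) -> pd.DataFrame:
    """Read a label table (patient_id, note_id, topic)."""
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def read_cdm(path) -> list[tuple[str, str]]:
    """Read CDM report lines as (patient_id, line) from a tab-separated file."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            pid, _, text = line.partition("\t")
            out.append((pid, text))
    return out
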