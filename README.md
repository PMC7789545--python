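# rwegm — real-world evidence mining of genetic-test utility from clinical notes

`rwegm` is a sentence-level NLP + biostatistics toolkit for studying how
genetic test results (the BRCA1/2 use case) are documented and acted upon in
unstructured electronic health records.  It is aimed at clinical-informatics
researchers who want to turn patient-linked note sentences into curated,
auditable genomic real-world data and then test downstream clinical
associations.

## What it computes

Given a corpus of patient-linked sentences, the pipeline:

1. **extracts** every sentence mentioning a target gene (word-boundary,
   case-insensitive), recognizes HUGO gene symbols and HGVS-style variant
   mentions by regular expression, masks non-target genes as `GENE` and
   variants as `MUTATION`, normalizes tokens (lowercase, suffix-rule
   lemmatization, stopword/punctuation/number removal) and collapses
   within-patient duplicates to the earliest instance;
2. **scores sentence universality** with sf-ipf,

       sf(s)  = #s / #sentences,      ipf(s) = log(N) / #patients-with-s,
       sf-ipf(s) = sf(s) · ipf(s)

   (low scores flag patient-specific, result-bearing sentences), and ranks
   topic-indicating words by pointwise mutual information
   `pmi(w,t) = log P(w,t) / (P(w)P(t))` with add-k smoothing;
3. **classifies** each sentence into one of seven clinical-context topics —
   Information, Evaluation, Insurance, Order, Negative, Positive, VUS — with
   a rule-based system (indicator lexicons + a nearest-gene proximity rule
   with a five-token window and negation flipping) and, in parallel, a
   bag-of-words random forest evaluated by stratified ten-fold
   cross-validation at seven-topic and four-topic granularity;
4. **curates** result sentences into a clinical-genomics data model
   (Hugo_Symbol, Variant_Type, Variant_Source, Variant_Pathogenicity,
   Variant_Classification, HGVS_Short, …), audits field-level completeness
   and note-vs-report capture rates, flags documentation discrepancies
   (gene switches, status flips) and builds topic × occurrence-rank
   timelines;
5. **tests the association** between BRCA1/2 mutation status and
   PARP-inhibitor discussion/prescription with an exact Fisher test for
   general r×c tables (probability-ordering two-sided p, full enumeration
   with a seeded Monte-Carlo fallback).

A synthetic-cohort generator (`rwegm.synthetic`) produces gold-labeled
notes, reference genetic reports, medication tables and injected
discrepancies with the statistical structure the pipeline assumes, since
real clinical notes cannot be shared.

## Worked example

The packaged worked-example cohort (`rwegm.synthetic.table1_fixture`) runs
the full extraction + audit path:

```python
from rwegm import synthetic, textprep, topic_rules, quality

fix = synthetic.table1_fixture()
kept = textprep.extract_target_sentences(fix.sentences)
ann = [textprep.annotate(r) for r in kept]
dedup = textprep.deduplicate_per_patient(ann)
records = topic_rules.extract_variant_records(dedup)

print(f"{len(dedup)} result sentences -> {len(records)} variant records")
for field, c in quality.completeness(records).items():
    print(f"{field:24s} {c.numerator:>3}/{c.denominator:<3} = {c.percent}%")
for status in ("positive", "vus"):
    cr = quality.capture_rate(fix.reference_reports, records, status)
    print(f"capture rate ({status}): {cr.n_matched}/{cr.n_reference} = {cr.percent}%")
```

prints

```
91 result sentences -> 91 variant records
Variant_Type               8/16  = 50.0%
Variant_Source            24/91  = 26.4%
Variant_Pathogenicity      7/16  = 43.8%
Variant_Classification     1/16  = 6.3%
HGVS_Short                 4/16  = 25.0%
capture rate (positive): 9/12 = 75.0%
capture rate (vus): 5/24 = 20.8%
```

i.e. among result-bearing Positive/VUS sentences only half carry a variant
type, a quarter an HGVS string and 6.3% a variant classification; 75% of
reference-positive patients but only 20.8% of reference-VUS patients have
their result documented in notes at all — the central data-quality finding
the audit is built to expose.

## Command line

Every stage is also a subcommand of the `rwegm` console script:

```bash
rwegm simulate --out sim/ --patients 196 --seed 7
rwegm extract --in sim/notes.jsonl --genes BRCA1,BRCA2 --out sentences.jsonl
rwegm score --in sim/notes.jsonl --out scores.csv
rwegm pmi --in sim/notes.jsonl --labels sim/gold_labels.csv --out pmi.csv
rwegm classify-rules --in sim/notes.jsonl --out labels.csv
rwegm classify-ml --in sim/notes.jsonl --labels sim/gold_labels.csv \
      --granularity 4 --folds 10 --seed 13 --report ml.json
rwegm extract-variants --in sim/notes.jsonl --out variants.csv
rwegm quality-report --variants variants.csv --reference sim/reports.csv --out quality.json
rwegm timeline --in sim/notes.jsonl --labels labels.csv --out matrix.csv
rwegm associate --sentences sim/notes.jsonl --labels labels.csv \
      --reference sim/reports.csv --meds sim/meds.csv --cdm sim/cdm.txt --out assoc.json
rwegm evaluate --gold sim/gold_labels.csv --pred labels.csv --out metrics.json
```

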