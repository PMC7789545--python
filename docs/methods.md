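# Methods

This note documents the models and procedures implemented in `rwegm`, the
parameter choices that matter, what the synthetic data does and does not
emulate, and the numerical conventions used throughout.

## Text preparation

Sentences are the unit of analysis: one record per patient-linked sentence
(patient id, note id, date, text).  When whole notes are supplied,
`textprep.split_sentences` applies a rule-based splitter on `.;!?` and
newlines with an abbreviation guard (titles, `e.g.`, and the `c.`/`p.`
prefixes of HGVS tokens).

Gene mentions are matched case-insensitively on word boundaries against an
editable HUGO-symbol dictionary (shipped with 23 cancer-relevant genes; the
full HUGO list can be substituted).  Variant mentions cover four regex
families: HGVS cDNA changes (`c.7759C>T`, optional spaces around `>`,
`c.68_69delAG`), three-letter protein changes (`p.Arg149Trp`), shorthand
protein changes (`S34F`), and the copy-number/rearrangement words
*amplification, deletion, rearrangement, truncation* — the words count as
variant mentions only within a 5-word window of a gene mention, since in
isolation they are usually non-genomic.

Masking replaces non-target gene mentions with `GENE` and variant mentions
with `MUTATION`; the target genes (BRCA1/BRCA2 by default) are preserved
verbatim.  Tokens are lowercased, lemmatized by deterministic suffix rules
(plural stripping, `-ing`/`-ed` removal with a curated exception list),
and filtered of stopwords, punctuation and digit-only tokens.  The suffix
lemmatizer trades linguistic fidelity for bit-reproducibility: it needs no
model download and maps the clinically relevant inflections (tested →
test, ordering → order) onto the rule lexicons.  Concept-vocabulary
filtering is an optional plain word list (off by default); a licensed
medical vocabulary can be plugged in without changing the pipeline shape.

Within-patient duplicates are collapsed on *normalized-text* identity,
keeping the earliest instance; date ties break toward the lexicographically
smallest note id.  Character offsets are 0-based half-open; token distance
between two mentions is the number of tokens strictly between them.

## Sentence universality (sf-ipf) and indicator discovery (PMI)

sf-ipf scores how boilerplate a sentence is: `sf(s)` is the fraction of
sentence instances equal to `s` (computed after per-patient deduplication,
so one instance per patient per sentence) and `ipf(s) = log(N)/n_s` with
`N` the cohort size and `n_s` the number of patients with the sentence.
The log is natural by default (configurable); `N` defaults to the number of
patients observed in the corpus but can be overridden with the full cohort
size when only a subset of patients has target sentences.  The review-pool
selector takes all sentences below a threshold (default 0.5) plus a seeded
random sample of the remainder, mirroring a stratified manual-review
workflow.

PMI between a word and a topic is estimated on per-sentence word
occurrences (a word counts once per sentence), with add-k smoothing over
the word × topic grid (default k = 0.5; with k = 0, zero-joint-count pairs
are omitted with a warning).  For disjoint topic vocabularies the score of
a topic-exclusive word reduces to −log P(t), which the tests use as a
closed-form check.

## Rule-based topic classification

Seven topics: Information, Evaluation, Insurance, Order, Negative,
Positive, VUS.  The rule engine distinguishes:

- **result indicators** — positivity (*positive, pathogenic, mutate,
  deleterious, actionable*), negativity (*negative, wildtype,
  unremarkable*) and VUS (*vus, unknown/uncertain significance*) terms.
  Each indicator binds to its nearest gene mention by token distance;
  the binding is rejected beyond a 5-token proximity window (ties go to the
  leftmost gene), and a negation cue (*no, not, without*) within 3 tokens
  before a positivity indicator flips it to negativity.  The window of 5 is
  counted as intervening normalized tokens; the negation window of 3 is
  this package's choice.
- **context indicators** — per-topic word lists (e.g. *insurance,
  coverage* for Insurance; *order, await, pend* for Order; *risk, family,
  history, hereditary* for Evaluation), with conditional indicators that
  only reinforce a co-occurring primary indicator.

A sentence with a bound result assertion gets the corresponding result
topic; otherwise the highest-priority topic with a matching indicator wins
(priority VUS > Positive > Negative > Insurance > Order > Evaluation >
Information — result topics are rarer and more specific); the fallback is
Information.  The shipped lexicon is a faithful skeleton seeded from
high-PMI indicator words and is meant to be extended per corpus via YAML; a
production rule set converges through iterative review, which no static
default can replicate.

Result sentences additionally yield a data-model row: Variant_Type is
inferred from the nearest variant mention's syntax (substitution → SNP,
ins/del/dup → INDEL, amplification/deletion terms → CNV, rearrangement
terms → Rearrangement); Variant_Pathogenicity is filled only from explicit
pathogenicity vocabulary (*pathogenic, actionable*, or a VUS indicator) —
a bare "positive" does not populate it, which is what makes field-level
completeness a meaningful audit; Variant_Source requires a literal
germline/somatic token; Variant_Classification requires a classification
keyword (missense, nonsense, splice site, frameshift, silent, intronic).
Absent fields stay empty — the expected degenerate outcome in routine
documentation.

## Machine-learning classification

Sentences are vectorized as token counts (vocabulary fitted on training
folds only; unseen test-fold tokens are ignored) and classified with a
random forest — chosen for interpretability via impurity-based feature
importance.  Defaults: 500 trees, √|vocab| features per split, no depth
cap; the test-suite and acceptance runs use 30–100 trees, which saturate
accuracy on the synthetic corpora.  Evaluation is stratified ten-fold
cross-validation aggregating out-of-fold predictions; classes smaller than
the fold count trigger a warning and degrade gracefully to best-effort
stratification.  Two granularities are reported: the full seven topics, and
a four-topic task where the context topics collapse into Information.
Overall metrics are reported two ways — micro (= accuracy for single-label
multiclass) and support-weighted macro — since different summaries suit
different downstream uses.  Feature importance reports mean impurity
decrease and the number of tree nodes splitting on each token.

## Quality auditing and timelines

Completeness is audited per field over the records where the field is
expected: Variant_Type, Variant_Pathogenicity, Variant_Classification and
HGVS_Short over Positive + VUS records; Variant_Source over all result
records (panel type implies it even for negatives).  Percentages are exact
rational fractions rounded half-up to one decimal.

Capture rate compares reference report tables (one status row per patient)
against note-derived records: a patient is captured when some extracted
record matches on gene symbol and status-compatible topic (pathogenic ↔
Positive, VUS ↔ VUS).  This lenient gene+status criterion is the default;
`strict=True` additionally requires the HGVS string to match.  Patient-level
capture and field-level completeness are deliberately separate statistics,
even though a report table may conflate them.

Discrepancy detection flags, per patient timeline, (a) *gene switches* —
the same positive/VUS status asserted for two different genes on different
dates — and (b) *status flips* — pathogenic vs wildtype for the same gene.
Flags carry both sentence provenances and are invariant to scan direction.

The topic × rank matrix counts, for every patient, the k-th dated encounter
(same-date ties broken by note id; every encounter counts, because result
topics are re-mentioned at follow-ups), then row-normalizes to percentages
so each topic row sums to 100.

## Association testing

Per-patient therapy status: *discussion* = an Information-topic sentence
containing a PARP-inhibitor lexicon term (olaparib, rucaparib, niraparib,
PARP, PARPi, and brand names — both the common spelling "Lynparza" and the
variant "Lyparza" are configured); *prescription* = a hit in the structured
medication table, a CDM report line, or a current-medications note section
located by a case-insensitive header regex.  Prescription implies
discussion in the three-way status (none / discussion only / discussion +
prescription); a prescription without any discussion is logged as a
validation warning.

The mutation-status × therapy-status table is tested with Fisher's exact
test for r×c tables using the probability-ordering (two-sided) criterion:
p is the sum of hypergeometric probabilities of all tables with the
observed margins whose probability is ≤ that of the observed table (within
relative tolerance 1e-7).  The implementation enumerates tables by rows
with the final two rows evaluated as a vectorized grid; zero-margin rows or
columns are dropped with a warning; degenerate 1×c tables give p = 1.
Above a workload bound (default 5·10⁷ grid cells) a seeded Monte-Carlo
estimate over margin-preserving permutations (default 10⁶ draws, reported
as (hits+1)/(draws+1)) replaces enumeration.  On 2×2 tables the method
coincides with the classical two-sided hypergeometric test, which the test
suite verifies against an independent implementation.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, not
clinical language.  Defaults mirror the study conditions of a 196-patient
women-cancer cohort: mutation prevalence 12/196 mutated, 24/196 VUS;
note-capture probability 0.75 for positives and 0.208 for VUS; ~42% of
sentence instances duplicated into later notes; field-level dropout of
variant details at the audited completeness complements (type 0.5, HGVS
0.75, pathogenicity wording 0.562, classification 0.937, source 0.736);
therapy-discussion probabilities 0.9/0.6/0.45 and
prescription-given-discussion 0.6/0.15/0.04 by mutation status, giving a
strong mutation → prescription gradient at cohort scale.  Each patient
follows a staged journey — Evaluation/Information (in either order), then
Order, optionally Insurance (30%), then 1–3 result mentions — with strictly
increasing dates, so Evaluation/Information concentrate at occurrence ranks
1–2 by construction.  Gene-switch discrepancies are injected at rate 0.05
among documented positive/VUS patients and recorded as gold.  An HGVS
mention implies an inferable variant type, so the independent type-term
probability is solved as (p_type − p_hgvs)/(1 − p_hgvs) to hit the target
type rate; VUS sentences always carry explicit pathogenicity wording (the
VUS indicator is the wording), so the pathogenicity dropout applies to
Positive sentences only.

Topic templates use disjoint content vocabularies, which is what makes the
end-to-end recovery tests sharp: rule-based accuracy ≥ 0.99 and perfect
discrepancy recovery on clean cohorts show internal consistency of
generator + pipeline, not expected performance on real notes, where
lexicons overlap, negation is harder, and documentation is far noisier.
The fixed worked-example cohort (`table1_fixture`) is engineered so the
full extraction path reproduces the audited fractions exactly (8/16 type,
7/16 pathogenicity, 1/16 classification, 4/16 HGVS, 24/91 source, 9/12 and
5/24 capture).

## Problem sizes and reproducibility

The acceptance script uses a 500-patient synthetic cohort (≈2700 unique
sentences), ten-fold CV with 80 trees, and full enumeration for the Fisher
test; these sizes saturate the measured properties while keeping runs
short.  All randomness — cohort generation, fold shuffling, forest
construction, Monte-Carlo sampling — flows from explicit integer seeds; no
global random state is used.

## Known limitations

- The default rule lexicon is a skeleton; real corpora require iterative
  lexicon curation against PMI rankings.
- Negation handling is a cue-window rule, not scope parsing; cross-sentence
  coreference and document-level result reconciliation are out of scope
  beyond the discrepancy flags.
- HGVS matching is by regex family, not a full HGVS grammar; no genomic
  coordinates or build liftover.
- The synthetic generator's disjoint vocabularies make classification
  easier than on real notes; its F1/accuracy figures are upper bounds.
- Kappa is unweighted (nominal labels); survival or dose/duration analyses
  of the therapy endpoint are not included.
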