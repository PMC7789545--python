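"""Sentence ingestion, gene/variant mention recognition, normalization and masking.

The pipeline starts from one record per patient-linked sentence. Gene symbols
(HUGO nomenclature) and variant mentions (HGVS-style cDNA/protein changes plus
copy-number / rearrangement terms near a gene) are located by regular
expression, then every gene symbol other than the target genes (BRCA1/BRCA2)
is masked as ``GENE`` and every variant mention as ``MUTATION``.  Tokens are
lowercased, lemmatized by deterministic suffix rules, and stripped of
stopwords, punctuation and digit-only tokens.  Within each patient, sentences
with identical normalized text are collapsed to the earliest instance.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from datetime import date as Date
from datetime import datetime
from importlib import resources
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

DEFAULT_TARGETS = frozenset({"BRCA1", "BRCA2"})

GENE_MASK = "GENE"
VARIANT_MASK = "MUTATION"

# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GeneMention:
    """A gene-symbol occurrence; ``span`` is a 0-based half-open char interval."""

    symbol: str
    span: tuple[int, int]
    is_target: bool


@dataclass(frozen=True)
class VariantMention:
    """A variant-nomenclature occurrence in raw text."""

    raw: str
    syntax_kind: str  # cdna | protein_3letter | protein_shorthand | cnv_term | rearrangement_term
    span: tuple[int, int]


@dataclass
class SentenceRecord:
    """One patient-linked clinical sentence and its derived annotations.

    ``tokens`` are the normalized (lowercase, lemmatized, stopword-free)
    tokens of the masked sentence; ``token_spans`` give the raw-text character
    span each token came from and ``token_genes`` the gene symbol behind a
    token when the token stands for a gene mention (masked or not).
    """

    patient_id: str
    note_id: str
    date: Optional[Date]
    raw_text: str
    tokens: list[str] = field(default_factory=list)
    masked_text: str = ""
    gene_mentions: list[GeneMention] = field(default_factory=list)
    variant_mentions: list[VariantMention] = field(default_factory=list)
    token_spans: list[tuple[int, int]] = field(default_factory=list)
    token_genes: list[Optional[str]] = field(default_factory=list)

    @property
    def normalized_text(self) -> str:
        return " ".join(self.tokens)


# ---------------------------------------------------------------------------
# packaged resources


def load_wordlist(name_or_path: str) -> frozenset[str]:
    """Load a one-token-per-line word list; ``#`` lines are comments."""
    try:
        text = resources.files("rwegm.data").joinpath(name_or_path).read_text()
    except (FileNotFoundError, TypeError):
        with open(name_or_path) as fh:
            text = fh.read()
    words = set()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.add(line.lower())
    return frozenset(words)


def default_stopwords() -> frozenset[str]:
    return load_wordlist("stopwords_en.txt")


def default_gene_dict() -> frozenset[str]:
    return frozenset(w.upper() for w in load_wordlist("gene_dict.txt"))


# ---------------------------------------------------------------------------
# sentence splitting (for whole notes)

_ABBREV = {"dr", "mr", "mrs", "ms", "vs", "st", "no", "e.g", "i.e", "approx", "fig", "al"}
_SPLIT_RE = re.compile(r"[.;!?\n]")


def split_sentences(text: str) -> list[str]:
    """Rule-based sentence splitter on ``[.;!?\\n]`` with an abbreviation guard.

    Periods inside HGVS tokens (``c.``/``p.``) and decimal numbers do not split.
    """
    out: list[str] = []
    start = 0
    for m in _SPLIT_RE.finditer(text):
        i = m.start()
        if m.group() == ".":
            before = text[start:i]
            word = re.search(r"([A-Za-z.]+)$", before)
            w = word.group(1).lower().rstrip(".") if word else ""
            if w in _ABBREV or w in {"c", "p"}:
                continue
            if i + 1 < len(text) and text[i - 1 : i].isdigit() and text[i + 1].isdigit():
                continue
        seg = text[start:i].strip()
        if seg:
            out.append(seg)
        start = m.end()
    tail = text[start:].strip()
    if tail:
        out.append(tail)
    return out


# ---------------------------------------------------------------------------
# target-sentence extraction


def _target_regex(targets: Iterable[str]) -> re.Pattern:
    alts = "|".join(re.escape(t) for t in sorted(targets, key=len, reverse=True))
    return re.compile(rf"\b(?:{alts})\b", re.IGNORECASE)


def extract_target_sentences(
    corpus: Iterable[SentenceRecord], targets: Iterable[str] = DEFAULT_TARGETS
) -> list[SentenceRecord]:
    """Keep the records whose raw text mentions a target gene.

    Matching is case-insensitive on word boundaries; input order is preserved.
    Records with a missing/unparseable date are rejected with a warning.
    """
    pat = _target_regex(targets)
    kept: list[SentenceRecord] = []
    for rec in corpus:
        if not rec.raw_text:
            continue
        if rec.date is None:
            logger.warning(
                "rejecting record %s/%s: unparseable date", rec.patient_id, rec.note_id
            )
            continue
        if pat.search(rec.raw_text):
            kept.append(rec)
    return kept


def parse_date(value) -> Optional[Date]:
    """Parse an ISO-8601 (or mm/dd/yyyy) date; return None when unparseable."""
    if isinstance(value, Date):
        return value
    if value is None:
        return None
    s = str(value).strip()
    for fmt in ("%Y-%m-%d", "%m/%d/%Y"):
        try:
            return datetime.strptime(s, fmt).date()
        except ValueError:
            pass
    return None


# ---------------------------------------------------------------------------
# mention recognition

# HGVS-style cDNA change: c.7759C>T (optional spaces around '>'), c.68_69delAG ...
_CDNA_RE = re.compile(
    r"c\.\s?[0-9]+(?:[+\-][0-9]+)?(?:_[0-9]+(?:[+\-][0-9]+)?)?\s*"
    r"(?:[ACGT]+\s*>\s*[ACGT]+|delins[ACGT]*|del[ACGT]*|ins[ACGT]+|dup[ACGT]*)"
)
# 3-letter protein change: p.Arg149Trp, p.(Gln1756fs), p.Trp31*
_PROT3_RE = re.compile(
    r"p\.\s?\(?(?:[A-Z][a-z]{2})[0-9]+(?:[A-Z][a-z]{2}|fs\*?[0-9]*|del|dup|ins[A-Za-z]*|\*)\)?"
)
# shorthand protein change: S34F, L858R (excludes gene-symbol shapes)
_SHORT_RE = re.compile(r"\b[A-Z][0-9]{2,5}(?:[A-Z]|\*|fs)\b")
_CNV_TERMS = {"amplification": "cnv_term", "deletion": "cnv_term"}
_REARR_TERMS = {"rearrangement": "rearrangement_term", "truncation": "rearrangement_term"}
_TERM_RE = re.compile(
    r"\b(amplification|deletion|rearrangement|truncation)s?\b", re.IGNORECASE
)
_WORD_RE = re.compile(r"[A-Za-z0-9]+(?:[./>_'\-][A-Za-z0-9]+)*")


def recognize_mentions(
    raw_text: str,
    gene_dict: Optional[Iterable[str]] = None,
    targets: Iterable[str] = DEFAULT_TARGETS,
    term_window: int = 5,
) -> tuple[list[GeneMention], list[VariantMention]]:
    """Locate gene symbols and variant mentions in ``raw_text``.

    Variant syntaxes covered: HGVS cDNA changes, 3-letter protein changes,
    shorthand protein changes, and the copy-number / rearrangement terms
    (amplification, deletion, rearrangement, truncation) when they lie within
    ``term_window`` words of a gene mention.  Returned mentions never overlap.
    """
    if not raw_text:
        return [], []
    genes_upper = {g.upper() for g in (gene_dict or default_gene_dict())}
    if not genes_upper:
        raise ValueError("gene_dict must be non-empty")
    targets_upper = {t.upper() for t in targets}
    gene_pat = _target_regex(genes_upper)

    gene_mentions = [
        GeneMention(
            symbol=m.group().upper(),
            span=(m.start(), m.end()),
            is_target=m.group().upper() in targets_upper,
        )
        for m in gene_pat.finditer(raw_text)
    ]
    gene_spans = [g.span for g in gene_mentions]

    def overlaps(span: tuple[int, int], spans: list[tuple[int, int]]) -> bool:
        return any(span[0] < e and s < span[1] for s, e in spans)

    variants: list[VariantMention] = []
    taken: list[tuple[int, int]] = list(gene_spans)
    for pat, kind in ((_CDNA_RE, "cdna"), (_PROT3_RE, "protein_3letter"), (_SHORT_RE, "protein_shorthand")):
        for m in pat.finditer(raw_text):
            span = (m.start(), m.end())
            if overlaps(span, taken):
                continue
            variants.append(VariantMention(raw=m.group(), syntax_kind=kind, span=span))
            taken.append(span)

    # CNV / rearrangement words count only within term_window words of a gene
    words = [(m.start(), m.end()) for m in _WORD_RE.finditer(raw_text)]

    def word_index(pos: int) -> int:
        for i, (s, e) in enumerate(words):
            if s <= pos < e:
                return i
        return -1

    gene_word_idx = [word_index(g.span[0]) for g in gene_mentions]
    for m in _TERM_RE.finditer(raw_text):
        span = (m.start(), m.end())
        if overlaps(span, taken):
            continue
        wi = word_index(m.start())
        if any(gi >= 0 and abs(wi - gi) - 1 <= term_window for gi in gene_word_idx):
            base = m.group(1).lower()
            kind = _CNV_TERMS.get(base) or _REARR_TERMS[base]
            variants.append(VariantMention(raw=m.group(), syntax_kind=kind, span=span))
            taken.append(span)

    variants.sort(key=lambda v: v.span)
    return gene_mentions, variants


# ---------------------------------------------------------------------------
# lemmatization

_LEMMA_EXCEPTIONS = {
    "was": "be", "were": "be", "is": "be", "are": "be", "been": "be",
    "has": "have", "had": "have",
    "found": "find", "women": "woman", "men": "man", "children": "child",
    "tested": "test", "testing": "test", "mutated": "mutate", "mutating": "mutate",
    "ordered": "order", "ordering": "order", "identified": "identify",
    "sequencing": "sequence", "sequenced": "sequence", "counseling": "counsel",
    "estimated": "estimate", "estimating": "estimate", "carrying": "carry",
    "carries": "carry", "carried": "carry", "denied": "deny", "discussed": "discuss",
    "documented": "document", "reported": "report", "recommended": "recommend",
    "detected": "detect", "confirmed": "confirm", "covered": "cover",
    "approved": "approve", "waiting": "wait", "awaiting": "await",
    "pending": "pend", "scheduled": "schedule", "scheduling": "schedule",
    "revised": "revise", "returned": "return", "received": "receive",
    "discussing": "discuss", "prescribed": "prescribe", "prescribing": "prescribe",
}

_KEEP_AS_IS = {"vus", "its", "this", "his", "hers", "brca1", "brca2", "gene", "mutation"}


def lemmatize(word: str) -> str:
    """Deterministic suffix-rule lemmatizer (plural stripping, -ing/-ed)."""
    w = word.lower()
    if w in _KEEP_AS_IS:
        return w
    if w in _LEMMA_EXCEPTIONS:
        return _LEMMA_EXCEPTIONS[w]
    if len(w) > 4 and w.endswith("ies"):
        return w[:-3] + "y"
    if len(w) > 4 and w.endswith("sses"):
        return w[:-2]
    if len(w) > 3 and w.endswith("es") and w[-3] in "sxz":
        return w[:-2]
    if len(w) > 3 and w.endswith("s") and not w.endswith(("ss", "us", "is")):
        return w[:-1]
    if len(w) > 5 and w.endswith("ing"):
        stem = w[:-3]
        if len(stem) > 2 and stem[-1] == stem[-2] and stem[-1] not in "aeiouls":
            stem = stem[:-1]
        return stem
    if len(w) > 4 and w.endswith("ed"):
        stem = w[:-2]
        if len(stem) > 2 and stem[-1] == stem[-2] and stem[-1] not in "aeiouls":
            stem = stem[:-1]
        return stem
    return w


# ---------------------------------------------------------------------------
# normalization + masking

_PUNCT_ONLY_RE = re.compile(r"^\W+$")
_DIGIT_ONLY_RE = re.compile(r"^[0-9]+$")
_ALPHA_RE = re.compile(r"[A-Za-z]")


def normalize_and_mask(
    record: SentenceRecord,
    stopwords: Optional[Iterable[str]] = None,
    vocab_filter: Optional[Iterable[str]] = None,
) -> SentenceRecord:
    """Mask non-target genes/variants and produce normalized tokens.

    ``masked_text`` substitutes non-target gene mentions with ``GENE`` and
    variant mentions with ``MUTATION`` in the raw text.  ``tokens`` is the
    normalized token sequence of the masked sentence, with ``token_genes``
    carrying the underlying gene symbol for gene-derived tokens so that
    downstream proximity rules can still bind assertions to specific genes.
    Applying the operation twice equals applying it once.
    """
    stop = frozenset(s.lower() for s in stopwords) if stopwords is not None else default_stopwords()
    vocab = frozenset(v.lower() for v in vocab_filter) if vocab_filter is not None else None

    raw = record.raw_text
    events: list[tuple[tuple[int, int], str, Optional[str]]] = []
    for g in record.gene_mentions:
        repl = g.symbol if g.is_target else GENE_MASK
        events.append((g.span, repl, g.symbol))
    for v in record.variant_mentions:
        events.append((v.span, VARIANT_MASK, None))
    events.sort(key=lambda e: e[0])

    # masked_text: raw text with spans substituted
    out, cursor = [], 0
    for (s, e), repl, _sym in events:
        out.append(raw[cursor:s])
        out.append(repl)
        cursor = e
    out.append(raw[cursor:])
    masked_text = "".join(out)

    # token stream with raw spans and gene provenance
    tokens: list[str] = []
    spans: list[tuple[int, int]] = []
    genes: list[Optional[str]] = []

    def add_word(word: str, span: tuple[int, int], gene: Optional[str]) -> None:
        if gene is not None or word in (GENE_MASK, VARIANT_MASK):
            tok = word.lower()
        else:
            if _PUNCT_ONLY_RE.match(word) or _DIGIT_ONLY_RE.match(word):
                return
            if not _ALPHA_RE.search(word):
                return
            tok = lemmatize(word)
            if tok in stop or not tok:
                return
            if vocab is not None and tok not in vocab:
                return
        tokens.append(tok)
        spans.append(span)
        genes.append(gene)

    cursor = 0
    for (s, e), repl, sym in events:
        for m in _WORD_RE.finditer(raw, cursor, s):
            add_word(m.group(), (m.start(), m.end()), None)
        add_word(repl, (s, e), sym)
        cursor = e
    for m in _WORD_RE.finditer(raw, cursor):
        add_word(m.group(), (m.start(), m.end()), None)

    return replace(
        record,
        masked_text=masked_text,
        tokens=tokens,
        token_spans=spans,
        token_genes=genes,
    )


def annotate(
    record: SentenceRecord,
    gene_dict: Optional[Iterable[str]] = None,
    stopwords: Optional[Iterable[str]] = None,
    vocab_filter: Optional[Iterable[str]] = None,
    targets: Iterable[str] = DEFAULT_TARGETS,
) -> SentenceRecord:
    """Convenience: recognize mentions then normalize and mask."""
    genes, variants = recognize_mentions(record.raw_text, gene_dict, targets)
    rec = replace(record, gene_mentions=genes, variant_mentions=variants)
    return normalize_and_mask(rec, stopwords, vocab_filter)


# ---------------------------------------------------------------------------
# per-patient deduplication


def deduplicate_per_patient(records: Sequence[SentenceRecord]) -> list[SentenceRecord]:
    """Collapse per-patient duplicates (identical normalized text) to the earliest.

    Date ties break toward the lexicographically smallest note_id.  Records of
    different patients never collapse.  Output order follows first appearance.
    """
    best: dict[tuple[str, str], SentenceRecord] = {}
    order: list[tuple[str, str]] = []
    for rec in records:
        key = (rec.patient_id, rec.normalized_text or rec.raw_text.strip().lower())
        cur = best.get(key)
        if cur is None:
            best[key] = rec
            order.append(key)
        elif (rec.date, rec.note_id) < (cur.date, cur.note_id):
            best[key] = rec
    return [best[k] for k in order]
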