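"""Rule-based seven-topic classification and result-assertion extraction.

Topics: Information, Evaluation, Insurance, Order, Negative, Positive, VUS.
The classifier works on normalized tokens.  Result topics are driven by
positivity/negativity/VUS indicators bound to the nearest gene mention by a
proximity rule (an indicator more than ``proximity_window`` tokens away from
every gene is not a result assertion); context topics fall out of per-topic
indicator word lists with a fixed priority order; the fallback is Information.
Result sentences additionally yield a structured variant record (gene,
pathogenicity, variant type, HGVS string, source, classification).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import yaml

from .quality import VariantRecord
from .textprep import SentenceRecord

TOPICS = ("Information", "Evaluation", "Insurance", "Order", "Negative", "Positive", "VUS")

_STATUS_BY_KIND = {"positivity": "pathogenic", "negativity": "wildtype", "vus": "vus"}
_TOPIC_BY_STATUS = {"pathogenic": "Positive", "wildtype": "Negative", "vus": "VUS"}


@dataclass
class RuleSet:
    """Topic-indicating word lists plus proximity/negation windows."""

    indicator_words: dict[str, list[str]] = field(default_factory=dict)
    conditional_indicators: dict[str, list[str]] = field(default_factory=dict)
    positivity_indicators: list[str] = field(default_factory=list)
    negativity_indicators: list[str] = field(default_factory=list)
    vus_indicators: list[str] = field(default_factory=list)
    negation_cues: list[str] = field(default_factory=lambda: ["no", "not", "without"])
    proximity_window: int = 5
    negation_window: int = 3
    priority_order: list[str] = field(default_factory=lambda: list(
        ("VUS", "Positive", "Negative", "Insurance", "Order", "Evaluation", "Information")))

    def __post_init__(self) -> None:
        if self.proximity_window < 1:
            raise ValueError("proximity_window must be >= 1")
        sets = [set(v) for v in self.indicator_words.values()]
        sets += [set(self.positivity_indicators), set(self.negativity_indicators),
                 set(self.vus_indicators)]
        for i, a in enumerate(sets):
            for b in sets[i + 1:]:
                if a & b:
                    raise ValueError(f"indicator sets overlap: {a & b}")

    @classmethod
    def from_yaml(cls, path_or_stream) -> "RuleSet":
        if hasattr(path_or_stream, "read"):
            cfg = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream) as fh:
                cfg = yaml.safe_load(fh)
        return cls(**cfg)

    @classmethod
    def default(cls) -> "RuleSet":
        text = resources.files("rwegm.data").joinpath("default_rules.yaml").read_text()
        return cls(**yaml.safe_load(text))

    def result_indicator_sets(self) -> dict[str, list[str]]:
        return {
            "positivity": self.positivity_indicators,
            "negativity": self.negativity_indicators,
            "vus": self.vus_indicators,
        }


@dataclass(frozen=True)
class ResultAssertion:
    """A positivity/negativity/VUS indicator bound to its nearest gene."""

    gene: str
    status: str  # pathogenic | wildtype | vus
    indicator_token: str
    distance: int
    indicator_index: int
    gene_index: int


def _phrase_hits(tokens: Sequence[str], phrases: Iterable[str]) -> list[tuple[int, int, str]]:
    """Occurrences of single- or multi-word indicator phrases in the token list.

    Returns (start index, length, phrase) triples.
    """
    hits = []
    for phrase in phrases:
        parts = phrase.split()
        n = len(parts)
        for i in range(len(tokens) - n + 1):
            if list(tokens[i : i + n]) == parts:
                hits.append((i, n, phrase))
    return hits


def assign_positivity(record: SentenceRecord, rules: Optional[RuleSet] = None) -> list[ResultAssertion]:
    """Bind each result indicator to its nearest gene mention.

    Token distance is the number of tokens strictly between indicator and
    gene (multi-word indicators measure from their nearest edge).  A binding
    farther than ``proximity_window`` is rejected; distance ties break toward
    the leftmost gene.  A negation cue within ``negation_window`` tokens
    before a positivity indicator flips it to a negativity (wildtype) one.
    Duplicate (gene, status) assertions collapse to the closest binding.
    """
    rules = rules or RuleSet.default()
    tokens = record.tokens
    gene_positions = [
        (i, sym) for i, sym in enumerate(record.token_genes or []) if sym is not None
    ]
    if not gene_positions:
        return []
    out: dict[tuple[str, str], ResultAssertion] = {}
    for kind, phrases in rules.result_indicator_sets().items():
        for start, length, phrase in _phrase_hits(tokens, phrases):
            status = _STATUS_BY_KIND[kind]
            if kind == "positivity":
                lo = max(0, start - rules.negation_window)
                if any(t in rules.negation_cues for t in tokens[lo:start]):
                    status = "wildtype"
            end = start + length - 1
            best: Optional[tuple[int, int, str]] = None  # (distance, gene_idx, symbol)
            for gi, sym in gene_positions:
                if gi < start:
                    dist = start - gi - 1
                elif gi > end:
                    dist = gi - end - 1
                else:
                    dist = 0
                if best is None or dist < best[0]:
                    best = (dist, gi, sym)
            assert best is not None
            dist, gi, sym = best
            if dist > rules.proximity_window:
                continue
            a = ResultAssertion(
                gene=sym, status=status, indicator_token=phrase,
                distance=dist, indicator_index=start, gene_index=gi,
            )
            key = (sym, status)
            if key not in out or a.distance < out[key].distance:
                out[key] = a
    return sorted(out.values(), key=lambda a: (a.gene_index, a.indicator_index))


def classify_rule(record: SentenceRecord, rules: Optional[RuleSet] = None) -> str:
    """Assign exactly one topic to a normalized sentence.

    Result assertions dominate; otherwise the highest-priority topic with a
    matching indicator wins (conditional indicators fire only alongside a
    primary indicator of the same topic); the fallback is Information.
    """
    rules = rules or RuleSet.default()
    assertions = assign_positivity(record, rules)
    if assertions:
        statuses = {a.status for a in assertions}
        for topic in rules.priority_order:
            if topic in _TOPIC_BY_STATUS.values() and any(
                _TOPIC_BY_STATUS[s] == topic for s in statuses
            ):
                return topic
    tokens = record.tokens
    result_words = {
        "VUS": rules.vus_indicators,
        "Positive": rules.positivity_indicators,
        "Negative": rules.negativity_indicators,
    }
    for topic in rules.priority_order:
        if topic in result_words:
            hits = _phrase_hits(tokens, result_words[topic])
            if not hits:
                continue
            if topic == "Positive":
                def _negated(start: int) -> bool:
                    lo = max(0, start - rules.negation_window)
                    return any(t in rules.negation_cues for t in tokens[lo:start])
                if all(_negated(s) for s, _l, _p in hits):
                    return "Negative"
            return topic
        primary = rules.indicator_words.get(topic, [])
        if _phrase_hits(tokens, primary):
            return topic
        # conditional indicators fire only alongside a primary indicator of
        # the same topic, so they never change the single-label outcome; they
        # exist for lexicon curation (PMI review) and coarse matching
    return "Information"


def classify_corpus(
    records: Sequence[SentenceRecord], rules: Optional[RuleSet] = None
) -> list[str]:
    rules = rules or RuleSet.default()
    return [classify_rule(r, rules) for r in records]


# ---------------------------------------------------------------------------
# variant-record extraction

_PATHOGENICITY_WORDS = {"pathogenic": "pathogenic", "actionable": "actionable",
                        "deleterious": "pathogenic"}
_CLASSIFICATION_PATTERNS: list[tuple[re.Pattern, str]] = [
    (re.compile(r"\bmissense\b", re.I), "Missense_Mutation"),
    (re.compile(r"\bnonsense\b", re.I), "Nonsense_Mutation"),
    (re.compile(r"\bsplice[\s_\-]?site\b", re.I), "Splice_Site"),
    (re.compile(r"\bframe[\s\-]?shift\b.{0,20}\bins", re.I), "Frame_Shift_Ins"),
    (re.compile(r"\bframe[\s\-]?shift\b", re.I), "Frame_Shift_Del"),
    (re.compile(r"\bsilent\b", re.I), "Silent"),
    (re.compile(r"\bintron(?:ic)?\b", re.I), "Intron"),
]
_INDEL_RE = re.compile(r"del|ins|dup|fs", re.I)


def _variant_type(mention) -> str:
    kind = mention.syntax_kind
    if kind == "cnv_term":
        return "CNV"
    if kind == "rearrangement_term":
        return "Rearrangement"
    if _INDEL_RE.search(mention.raw):
        return "INDEL"
    return "SNP"


def _clean_hgvs(raw: str) -> str:
    return re.sub(r"\s*([>._])\s*", r"\1", raw).replace(" ", "")


def extract_variant_record(
    record: SentenceRecord, assertion: ResultAssertion
) -> VariantRecord:
    """Populate a clinical-genomics data-model row from a result sentence.

    Absent information leaves fields empty — the expected degenerate outcome
    in routine documentation.  Variant_Type is inferred from the nearest
    variant mention's syntax (substitutions -> SNP, ins/del/dup -> INDEL,
    amplification/deletion terms -> CNV, rearrangement terms ->
    Rearrangement); Variant_Pathogenicity is filled only when explicit
    pathogenicity vocabulary (pathogenic/actionable/VUS) occurs, not from a
    bare "positive"; Variant_Source needs a literal germline/somatic token.
    """
    tokens = record.tokens
    topic = _TOPIC_BY_STATUS[assertion.status]

    pathogenicity = ""
    if assertion.status == "vus":
        pathogenicity = "VUS"
    else:
        for t in tokens:
            if t in _PATHOGENICITY_WORDS:
                pathogenicity = _PATHOGENICITY_WORDS[t]
                break

    source = ""
    for t in tokens:
        if t in ("germline", "somatic"):
            source = t
            break

    classification = ""
    for pat, value in _CLASSIFICATION_PATTERNS:
        if pat.search(record.raw_text):
            classification = value
            break

    # nearest variant mention to the asserted gene (character distance)
    gene_span = None
    for g in record.gene_mentions:
        if g.symbol == assertion.gene:
            gene_span = g.span
            break
    vtype, hgvs = "", ""
    if record.variant_mentions:
        def char_dist(m) -> int:
            if gene_span is None:
                return m.span[0]
            return min(abs(m.span[0] - gene_span[1]), abs(gene_span[0] - m.span[1]))
        nearest = min(record.variant_mentions, key=char_dist)
        vtype = _variant_type(nearest)
        hgvs_candidates = [
            m for m in record.variant_mentions
            if m.syntax_kind in ("cdna", "protein_3letter", "protein_shorthand")
        ]
        if hgvs_candidates:
            hgvs = _clean_hgvs(min(hgvs_candidates, key=char_dist).raw)

    return VariantRecord(
        Hugo_Symbol=assertion.gene,
        Variant_Type=vtype,
        Variant_Source=source,
        Variant_Pathogenicity=pathogenicity,
        Variant_Classification=classification,
        HGVS_Short=hgvs,
        Pathogeneity_Report_Date=record.date.isoformat() if record.date else "",
        De_sample_ID=record.patient_id,
        patient_id=record.patient_id,
        note_id=record.note_id,
        date=record.date,
        topic=topic,
        is_negative=assertion.status == "wildtype",
    )


def extract_variant_records(
    records: Sequence[SentenceRecord], rules: Optional[RuleSet] = None
) -> list[VariantRecord]:
    """Run assertion binding over a corpus and emit one record per assertion."""
    rules = rules or RuleSet.default()
    out = []
    for rec in records:
        for a in assign_positivity(rec, rules):
            out.append(extract_variant_record(rec, a))
    return out
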