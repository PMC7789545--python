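"""Mention recognition, masking, normalization and deduplication."""

import datetime as dt
import random
import re

import pytest

from rwegm import textprep
from rwegm.textprep import SentenceRecord, parse_date


def rec(text, patient="P1", note="N1", date="2018-01-01"):
    return SentenceRecord(patient, note, parse_date(date), text)


class TestExtractTargetSentences:
    @pytest.mark.parametrize("text,kept", [
        ("Patient tested positive for BRCA1 mutation.", True),
        ("Family history of colon cancer.", False),
        ("brca2 VUS reported", True),            # case-insensitive
        ("BRCA10 is not a target", False),        # word boundary
        ("the BRCA1-related pathway", True),      # hyphen is a boundary
    ])
    def test_membership(self, text, kept):
        out = textprep.extract_target_sentences([rec(text)])
        assert bool(out) is kept

    def test_order_preserved_and_bad_date_rejected(self, caplog):
        records = [rec("BRCA1 a", note="N1"), rec("no target", note="N2"),
                   rec("BRCA2 b", note="N3"),
                   SentenceRecord("P1", "N4", None, "BRCA1 undated")]
        out = textprep.extract_target_sentences(records)
        assert [r.note_id for r in out] == ["N1", "N3"]

    def test_matches_brute_force_boundary_oracle(self):
        rng = random.Random(42)
        words = ["BRCA1", "brca2", "BRCA10", "EGFR", "cancer", "xBRCA1", "BRCA2,"]
        sentences = [" ".join(rng.choices(words, k=rng.randint(2, 8)))
                     for _ in range(50)]
        oracle = re.compile(r"\b(?:BRCA1|BRCA2)\b", re.I)
        records = [rec(s, note=f"N{i}") for i, s in enumerate(sentences)]
        out = {r.note_id for r in textprep.extract_target_sentences(records)}
        expect = {r.note_id for r in records if oracle.search(r.raw_text)}
        assert out == expect


class TestRecognizeMentions:
    def test_gene_plus_protein_change(self):
        genes, variants = textprep.recognize_mentions("pathogenic BRCA2 p.Arg149Trp")
        assert [(g.symbol, g.is_target) for g in genes] == [("BRCA2", True)]
        assert [(v.raw, v.syntax_kind) for v in variants] == [("p.Arg149Trp", "protein_3letter")]

    def test_cdna_with_spaces(self):
        _, variants = textprep.recognize_mentions("c.7759C > T detected near BRCA2")
        assert variants[0].syntax_kind == "cdna"
        assert variants[0].raw == "c.7759C > T"

    def test_empty_input(self):
        assert textprep.recognize_mentions("") == ([], [])

    @pytest.mark.parametrize("text,kinds", [
        ("BRCA1 c.68_69delAG found", ["cdna"]),
        ("EGFR L858R present", ["protein_shorthand"]),
        ("BRCA2 amplification seen", ["cnv_term"]),
        ("BRCA1 rearrangement identified", ["rearrangement_term"]),
        ("an amplification with no nearby gene mention in this span of text at all", []),
        ("truncation far from the nearest gene which is way over here: BRCA1", []),
    ])
    def test_variant_kinds(self, text, kinds):
        _, variants = textprep.recognize_mentions(text)
        assert [v.syntax_kind for v in variants] == kinds

    def test_spans_within_bounds_and_non_overlapping(self):
        text = "BRCA1 c.68_69delAG and EGFR L858R with amplification"
        genes, variants = textprep.recognize_mentions(text)
        spans = sorted([g.span for g in genes] + [v.span for v in variants])
        for s, e in spans:
            assert 0 <= s < e <= len(text)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_agrees_with_regex_scan_oracle(self):
        """Gene recognition equals a brute-force per-symbol scan on 100 sentences."""
        rng = random.Random(7)
        vocab = ["BRCA1", "BRCA2", "EGFR", "TP53", "ATM", "negative", "mutation",
                 "p.Arg149Trp", "c.7759C>T", "test", "pathogenic"]
        genes_dict = textprep.default_gene_dict()
        for i in range(100):
            text = " ".join(rng.choices(vocab, k=rng.randint(3, 10)))
            genes, _ = textprep.recognize_mentions(text)
            found = sorted((g.span, g.symbol) for g in genes)
            expect = sorted(
                ((m.start(), m.end()), sym)
                for sym in genes_dict
                for m in re.finditer(rf"\b{sym}\b", text, re.I)
            )
            assert found == expect


class TestNormalizeAndMask:
    def test_masks_nontarget_gene_and_variant(self, make_record):
        r = make_record("EGFR L858R was negative")
        assert r.masked_text == "GENE MUTATION was negative"

    def test_target_gene_preserved(self, make_record):
        r = make_record("BRCA1 c.68_69delAG pathogenic")
        assert r.masked_text == "BRCA1 MUTATION pathogenic"

    def test_tokens_normalized(self, make_record):
        r = make_record("She was tested for BRCA2 mutations.")
        assert r.tokens == ["test", "brca2", "mutation"]

    def test_token_invariants(self, make_record):
        r = make_record("The 3 BRCA1 Results were POSITIVE, costing $500!")
        stop = textprep.default_stopwords()
        for t in r.tokens:
            assert t == t.lower()
            assert t not in stop
            assert not t.isdigit()

    def test_masked_text_clean_of_other_symbols(self, make_record):
        r = make_record("TP53 and EGFR negative but BRCA2 p.Ser34Phe positive")
        assert "TP53" not in r.masked_text and "EGFR" not in r.masked_text
        assert "p.Ser34Phe" not in r.masked_text
        assert "BRCA2" in r.masked_text

    def test_idempotent(self, make_record):
        r1 = make_record("EGFR L858R was negative for BRCA1 screening")
        r2 = textprep.normalize_and_mask(r1)
        assert r1.tokens == r2.tokens
        assert r1.masked_text == r2.masked_text

    def test_vocab_filter(self):
        r = SentenceRecord("P1", "N1", dt.date(2018, 1, 1), "BRCA1 screening was negative")
        genes, variants = textprep.recognize_mentions(r.raw_text)
        r.gene_mentions, r.variant_mentions = genes, variants
        out = textprep.normalize_and_mask(r, vocab_filter={"negative"})
        assert out.tokens == ["brca1", "negative"]  # gene tokens exempt


class TestDeduplicate:
    def test_keeps_earliest_within_patient(self, make_record):
        a = make_record("BRCA1 test was ordered.", date="2017-01-01", note="N2")
        b = make_record("BRCA1 test was ordered.", date="2017-06-01", note="N1")
        out = textprep.deduplicate_per_patient([b, a])
        assert len(out) == 1 and out[0].date == dt.date(2017, 1, 1)

    def test_date_tie_breaks_on_note_id(self, make_record):
        a = make_record("BRCA1 test ordered.", date="2017-01-01", note="N2")
        b = make_record("BRCA1 test ordered.", date="2017-01-01", note="N1")
        assert textprep.deduplicate_per_patient([a, b])[0].note_id == "N1"

    def test_cross_patient_duplicates_retained(self, make_record):
        a = make_record("BRCA1 test ordered.", patient="A")
        b = make_record("BRCA1 test ordered.", patient="B")
        assert len(textprep.deduplicate_per_patient([a, b])) == 2

    def test_counts_match_brute_force_grouping(self, make_record):
        # 12 records with 3 within-patient duplicate pairs -> 9 survivors
        recs = []
        texts = ["BRCA1 alpha test", "BRCA1 beta test", "BRCA1 gamma test"]
        i = 0
        for p in ("A", "B", "C"):
            for t in texts:
                recs.append(make_record(t, patient=p, note=f"N{i}",
                                        date=f"2017-0{i % 9 + 1}-01"))
                i += 1
        for p, t in (("A", texts[0]), ("B", texts[1]), ("C", texts[2])):
            recs.append(make_record(t, patient=p, note=f"N{i}", date="2018-01-01"))
            i += 1
        out = textprep.deduplicate_per_patient(recs)
        assert len(out) == 9
        brute = {(r.patient_id, r.normalized_text) for r in recs}
        assert len(out) == len(brute)

    def test_order_invariance_and_never_grows(self, make_record):
        rng = random.Random(3)
        recs = [make_record(t, patient=p, note=f"N{i}", date=f"2017-01-{d:02d}")
                for i, (p, t, d) in enumerate(
                    (rng.choice("AB"), rng.choice(["BRCA1 x", "BRCA2 y", "BRCA1 z"]),
                     rng.randint(1, 28)) for _ in range(30))]
        out1 = textprep.deduplicate_per_patient(recs)
        shuffled = recs[:]
        rng.shuffle(shuffled)
        out2 = textprep.deduplicate_per_patient(shuffled)
        key = lambda r: (r.patient_id, r.normalized_text, r.date, r.note_id)
        assert sorted(map(key, out1)) == sorted(map(key, out2))
        assert len(out1) <= len(recs)


class TestPropertyInvariants:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.text(max_size=80))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_annotation_total_and_idempotent(self, text):
        """Annotation never crashes on arbitrary text, spans stay in bounds,
        and re-normalizing an annotated record is a no-op."""
        ann = textprep.annotate(SentenceRecord("P", "N", dt.date(2018, 1, 1), text))
        again = textprep.normalize_and_mask(ann)
        assert again.tokens == ann.tokens
        assert again.masked_text == ann.masked_text
        for s, e in ann.token_spans:
            assert 0 <= s <= e <= len(text)

    @given(st.lists(st.tuples(st.sampled_from("AB"),
                              st.sampled_from(["BRCA1 x", "BRCA2 y z", "BRCA1 w"]),
                              st.integers(1, 28)), max_size=25))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_dedup_idempotent_and_shrinking(self, triples):
        recs = [textprep.annotate(SentenceRecord(p, f"N{i}", dt.date(2017, 1, d), t))
                for i, (p, t, d) in enumerate(triples)]
        once = textprep.deduplicate_per_patient(recs)
        twice = textprep.deduplicate_per_patient(once)
        assert len(once) <= len(recs)
        assert [r.note_id for r in twice] == [r.note_id for r in once]


class TestSplitSentences:
    def test_guards_abbreviations_and_hgvs(self):
        text = "Seen by Dr. Smith today. BRCA1 c.7759C>T was found; follow up later."
        out = textprep.split_sentences(text)
        assert out == ["Seen by Dr. Smith today",
                       "BRCA1 c.7759C>T was found", "follow up later"]
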