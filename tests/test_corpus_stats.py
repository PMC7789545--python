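"""sf-ipf scoring and PMI indicator discovery against hand/brute-force oracles."""

import datetime as dt
import math
import random
from collections import Counter, defaultdict

import pytest

from rwegm import corpus_stats
from rwegm.textprep import SentenceRecord


def rec(text, patient, note="N1"):
    r = SentenceRecord(patient, note, dt.date(2018, 1, 1), text)
    r.tokens = text.split()
    return r


class TestSfIpf:
    def test_single_sentence_single_patient(self):
        scores = corpus_stats.sf_ipf([rec("a b", "P1")])
        s = scores[0]
        assert (s.sf, s.ipf, s.score) == (1.0, 0.0, 0.0)

    def test_hand_computed_example(self):
        # 20 instances, 100-patient cohort; sentence s has 4 instances in 4
        # patients -> sf = 0.2, ipf = ln(100)/4, score ~ 0.2303
        records = [rec("shared sentence", f"P{i}", f"N{i}") for i in range(4)]
        records += [rec(f"unique {i}", f"Q{i}", f"M{i}") for i in range(16)]
        scores = {s.text: s for s in corpus_stats.sf_ipf(records, n_patients=100)}
        s = scores["shared sentence"]
        assert s.sf == pytest.approx(0.2)
        assert s.ipf == pytest.approx(math.log(100) / 4)
        assert s.score == pytest.approx(0.2 * math.log(100) / 4)

    def test_equal_frequencies_give_equal_sf(self):
        records = [rec(f"s{i}", f"P{i}") for i in range(5)]
        scores = corpus_stats.sf_ipf(records)
        assert all(s.sf == pytest.approx(1 / 5) for s in scores)

    def test_sf_sums_to_one_and_matches_counting_oracle(self):
        rng = random.Random(11)
        pool = [f"sentence {c}" for c in "abcdef"]
        records = [rec(rng.choice(pool), f"P{rng.randint(1, 9)}", f"N{i}")
                   for i in range(60)]
        scores = corpus_stats.sf_ipf(records)
        assert sum(s.sf for s in scores) == pytest.approx(1.0)
        # independent two-pass oracle
        counts = Counter(r.normalized_text for r in records)
        pats = defaultdict(set)
        for r in records:
            pats[r.normalized_text].add(r.patient_id)
        n_pat = len({r.patient_id for r in records})
        for s in scores:
            assert s.sf == pytest.approx(counts[s.text] / 60)
            assert s.ipf == pytest.approx(math.log(n_pat) / len(pats[s.text]))
            assert s.score == pytest.approx(s.sf * s.ipf)

    def test_monotone_in_patient_spread(self):
        # same sf, more patients -> strictly lower score
        a = [rec("x y", "P1", "N1"), rec("x y", "P1", "N2")]
        b = [rec("x y", "P1", "N1"), rec("x y", "P2", "N2")]
        pad = [rec(f"pad {i}", f"Q{i}") for i in range(3)]
        sa = {s.text: s for s in corpus_stats.sf_ipf(a + pad, n_patients=10)}["x y"]
        sb = {s.text: s for s in corpus_stats.sf_ipf(b + pad, n_patients=10)}["x y"]
        assert sa.sf == sb.sf
        assert sb.score < sa.score

    def test_empty_corpus_raises(self):
        with pytest.raises(ValueError, match="empty corpus"):
            corpus_stats.sf_ipf([])


class TestSelectUniversal:
    def _scores(self, values):
        return [corpus_stats.SfIpfScore(f"k{i}", f"t{i}", 0.1, 1.0, v, 1, 1)
                for i, v in enumerate(values)]

    def test_threshold_split(self):
        below, _ = corpus_stats.select_universal(self._scores([0.1, 0.6]), 0.5, 1, 0)
        assert [s.score for s in below] == [0.1]

    def test_deterministic_given_seed(self):
        scores = self._scores([i / 100 for i in range(100)])
        _, s1 = corpus_stats.select_universal(scores, 0.2, 10, seed=4)
        _, s2 = corpus_stats.select_universal(scores, 0.2, 10, seed=4)
        assert [x.sentence_key for x in s1] == [x.sentence_key for x in s2]

    def test_sample_without_replacement(self):
        scores = self._scores([1 + i for i in range(636)])
        _, sample = corpus_stats.select_universal(scores, 0.5, 50, seed=9)
        keys = [s.sentence_key for s in sample]
        assert len(keys) == 50 and len(set(keys)) == 50

    def test_small_remainder_returned_whole(self):
        scores = self._scores([0.6, 0.7])
        _, sample = corpus_stats.select_universal(scores, 0.5, 50, seed=0)
        assert len(sample) == 2


class TestPmi:
    def test_exclusive_word_closed_form(self):
        # word in 5 of 100 token-occurrences, all in topic T (10 of 100):
        # pmi = log((5/100) / ((5/100)(10/100))) = log(10)
        labeled = []
        for i in range(5):
            labeled.append((rec("w f", f"P{i}", f"N{i}"), "T"))
        for i in range(45):
            labeled.append((rec(f"u{i % 20} x{i}"[:60], f"P{i}", f"M{i}"), "U"))
        # topic T: 5 sentences x 2 tokens = 10 of 100 total token occurrences
        entries = corpus_stats.pmi_table(labeled, smoothing_k=0)
        total = sum(len(set(r.tokens)) for r, _ in labeled)
        assert total == 100
        e = next(x for x in entries if x.word == "w" and x.topic == "T")
        assert e.pmi == pytest.approx(math.log(10))

    def test_disjoint_vocabulary_closed_form(self):
        # with k=0, every topic-exclusive word has pmi = -log P(t)
        labeled = [(rec("a b", f"P{i}", f"N{i}"), "T1") for i in range(3)]
        labeled += [(rec("c d e", f"Q{i}", f"M{i}"), "T2") for i in range(2)]
        entries = corpus_stats.pmi_table(labeled, smoothing_k=0)
        total = 3 * 2 + 2 * 3
        for e in entries:
            p_t = e.count_t / total
            assert e.pmi == pytest.approx(-math.log(p_t))

    def test_uniform_word_pmi_near_zero(self):
        # word spread across topics proportionally to topic sizes
        labeled = [(rec("w filler1", f"P{i}", f"N{i}"), "A") for i in range(4)]
        labeled += [(rec("w filler2", f"Q{i}", f"M{i}"), "B") for i in range(4)]
        entries = corpus_stats.pmi_table(labeled, smoothing_k=0)
        for e in entries:
            if e.word == "w":
                assert abs(e.pmi) < 1e-12

    def test_brute_force_oracle_with_smoothing(self):
        rng = random.Random(5)
        topics = ["A", "B", "C"]
        vocab = list("pqrstuv")
        labeled = []
        for i in range(40):
            words = rng.sample(vocab, k=rng.randint(1, 4))
            labeled.append((rec(" ".join(words), f"P{i}", f"N{i}"), rng.choice(topics)))
        k = 0.5
        entries = corpus_stats.pmi_table(labeled, smoothing_k=k)
        # independent recount
        c_wt, c_w, c_t = Counter(), Counter(), Counter()
        for r, t in labeled:
            for w in set(r.tokens):
                c_wt[(w, t)] += 1
                c_w[w] += 1
                c_t[t] += 1
        V, T, C = len(c_w), len(set(t for _, t in labeled)), sum(c_t.values())
        denom = C + k * V * T
        for e in entries:
            p_wt = (c_wt[(e.word, e.topic)] + k) / denom
            p_w = (c_w[e.word] + k * T) / denom
            p_t = (c_t[e.topic] + k * V) / denom
            assert e.pmi == pytest.approx(math.log(p_wt / (p_w * p_t)))

    def test_sorted_descending_within_topic(self):
        labeled = [(rec("a b c", "P1", "N1"), "T"), (rec("a d", "P2", "N2"), "U")]
        entries = corpus_stats.pmi_table(labeled)
        by_topic = defaultdict(list)
        for e in entries:
            by_topic[e.topic].append(e.pmi)
        for vals in by_topic.values():
            assert vals == sorted(vals, reverse=True)

    def test_evaluation_slot_words_recovered(self, annotated_cohort):
        """Evaluation-exclusive words (family/history/hereditary) score highest
        for Evaluation on the mirrored synthetic corpus."""
        records, labels = annotated_cohort
        entries = corpus_stats.pmi_table(list(zip(records, labels)))
        best = {}
        for e in entries:
            if e.word in ("family", "history", "hereditary"):
                if e.word not in best or e.pmi > best[e.word][1]:
                    best[e.word] = (e.topic, e.pmi)
        assert all(best[w][0] == "Evaluation" for w in ("family", "history", "hereditary"))
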