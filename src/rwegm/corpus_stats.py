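"""Sentence-universality (sf-ipf) scores and PMI topic-indicator discovery.

sf-ipf mirrors tf-idf at the sentence/patient level:

    sf(s)  = (# instances of sentence s) / (total # sentence instances)
    ipf(s) = log(total # patients N) / (# patients with sentence s)
    sf-ipf(s) = sf(s) * ipf(s)

Low sf-ipf marks boilerplate-free, patient-specific sentences — the ones most
likely to carry actual genetic-test results.  PMI between a word and a topic,

    pmi(w, t) = log[ P(w, t) / (P(w) P(t)) ],

estimated on per-sentence word occurrences with add-k smoothing, ranks
topic-indicating words for rule development.
"""

from __future__ import annotations

import hashlib
import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .textprep import SentenceRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SfIpfScore:
    sentence_key: str
    text: str
    sf: float
    ipf: float
    score: float
    n_patients_with: int
    count: int


@dataclass(frozen=True)
class PmiEntry:
    word: str
    topic: str
    pmi: float
    count_wt: int
    count_w: int
    count_t: int


def sentence_key(normalized_text: str) -> str:
    return hashlib.sha1(normalized_text.encode()).hexdigest()[:16]


def sf_ipf(
    records: Sequence[SentenceRecord],
    log_base: float = math.e,
    n_patients: Optional[int] = None,
) -> list[SfIpfScore]:
    """Score every unique normalized sentence; one entry per unique sentence.

    ``records`` are typically the per-patient deduplicated sentences, so a
    sentence shared by k patients contributes k instances.  The ipf log
    defaults to the natural log (``log_base`` configurable).  ``n_patients``
    overrides the cohort size N when the cohort is larger than the set of
    patients with target sentences.
    """
    if not records:
        raise ValueError("empty corpus")
    total = len(records)
    if n_patients is None:
        n_patients = len({r.patient_id for r in records})
    counts: Counter[str] = Counter()
    patients: dict[str, set[str]] = defaultdict(set)
    texts: dict[str, str] = {}
    for r in records:
        t = r.normalized_text or r.raw_text.strip().lower()
        counts[t] += 1
        patients[t].add(r.patient_id)
        texts[t] = t
    log_n = math.log(n_patients) / math.log(log_base)
    out = []
    for t, c in counts.items():
        npat = len(patients[t])
        sf = c / total
        ipf = log_n / npat
        out.append(
            SfIpfScore(
                sentence_key=sentence_key(t),
                text=texts[t],
                sf=sf,
                ipf=ipf,
                score=sf * ipf,
                n_patients_with=npat,
                count=c,
            )
        )
    out.sort(key=lambda s: (s.score, s.sentence_key))
    return out


def select_universal(
    scores: Sequence[SfIpfScore],
    threshold: float = 0.5,
    n_random: int = 50,
    seed: int = 0,
) -> tuple[list[SfIpfScore], list[SfIpfScore]]:
    """Split scores into the below-threshold set plus a seeded random sample
    of the remainder (without replacement); mirrors the stratified review
    pool used to seed topic definitions."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    below = [s for s in scores if s.score < threshold]
    rest = sorted(
        (s for s in scores if s.score >= threshold), key=lambda s: s.sentence_key
    )
    if len(rest) <= n_random:
        return below, rest
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(rest), size=n_random, replace=False)
    return below, [rest[i] for i in sorted(idx)]


def pmi_table(
    labeled: Iterable[tuple[SentenceRecord, str]],
    smoothing_k: float = 0.5,
    topics: Optional[Sequence[str]] = None,
) -> list[PmiEntry]:
    """PMI of every (word, topic) pair, sorted per topic by descending PMI.

    A word is counted once per sentence occurrence.  Probabilities use add-k
    smoothing over the word x topic grid; with ``smoothing_k == 0`` pairs with
    zero joint count are omitted (log undefined) with a warning.
    """
    if smoothing_k < 0:
        raise ValueError("smoothing_k must be >= 0")
    c_wt: Counter[tuple[str, str]] = Counter()
    c_w: Counter[str] = Counter()
    c_t: Counter[str] = Counter()
    seen_topics: list[str] = []
    for rec, topic in labeled:
        if topic is None:
            raise ValueError("every record must carry a topic label")
        if topic not in seen_topics:
            seen_topics.append(topic)
        for w in set(rec.tokens):
            c_wt[(w, topic)] += 1
            c_w[w] += 1
            c_t[topic] += 1
    if not c_w:
        raise ValueError("empty corpus")
    topic_list = list(topics) if topics is not None else seen_topics
    vocab = sorted(c_w)
    total = sum(c_t.values())
    k = smoothing_k
    denom = total + k * len(vocab) * len(topic_list)
    entries = []
    omitted = 0
    for t in topic_list:
        for w in vocab:
            joint = c_wt.get((w, t), 0)
            if k == 0 and joint == 0:
                omitted += 1
                continue
            p_wt = (joint + k) / denom
            p_w = (c_w[w] + k * len(topic_list)) / denom
            p_t = (c_t[t] + k * len(vocab)) / denom
            entries.append(
                PmiEntry(
                    word=w,
                    topic=t,
                    pmi=math.log(p_wt / (p_w * p_t)),
                    count_wt=joint,
                    count_w=c_w[w],
                    count_t=c_t[t],
                )
            )
    if omitted:
        logger.warning("omitted %d zero-joint-count pairs (k=0)", omitted)
    entries.sort(key=lambda e: (e.topic, -e.pmi, e.word))
    return entries


def top_indicators(entries: Sequence[PmiEntry], n: int = 10) -> dict[str, list[str]]:
    """Top-n PMI words per topic (entries assumed sorted as from pmi_table)."""
    out: dict[str, list[str]] = defaultdict(list)
    for e in entries:
        if len(out[e.topic]) < n:
            out[e.topic].append(e.word)
    return dict(out)
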