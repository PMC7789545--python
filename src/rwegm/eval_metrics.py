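"""Precision / recall / F-measure and Cohen's kappa.

Metrics are computed in exact rational arithmetic and rounded only for
reporting:

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F         = 2 TP / (2 TP + FP + FN)

Kappa is the unweighted Cohen's kappa for nominal labels,
kappa = (p_o - p_e) / (1 - p_e), with expected agreement p_e from the two
raters' marginal label frequencies.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Hashable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassCounts:
    true_positive: int
    false_positive: int
    false_negative: int
    true_negative: int = 0


def prf(counts: ClassCounts, ndigits: Optional[int] = None) -> tuple[float, float, float]:
    """(precision, recall, F-measure); zero denominators yield NaN + warning."""
    tp, fp, fn = counts.true_positive, counts.false_positive, counts.false_negative

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            logger.warning("%s undefined (zero denominator)", name)
            return math.nan
        return float(Fraction(num, den))

    p = _ratio(tp, tp + fp, "precision")
    r = _ratio(tp, tp + fn, "recall")
    f = _ratio(2 * tp, 2 * tp + fp + fn, "f_measure")
    if ndigits is not None:
        p, r, f = (round(x, ndigits) if not math.isnan(x) else x for x in (p, r, f))
    return p, r, f


def confusion_counts(
    gold: Sequence[Hashable], pred: Sequence[Hashable]
) -> dict[Hashable, ClassCounts]:
    """Per-class one-vs-rest counts from parallel single-label sequences."""
    if len(gold) != len(pred):
        raise ValueError("gold and pred must have equal length")
    labels = sorted(set(gold) | set(pred), key=str)
    n = len(gold)
    out = {}
    for lab in labels:
        tp = sum(1 for g, p in zip(gold, pred) if g == lab and p == lab)
        fp = sum(1 for g, p in zip(gold, pred) if g != lab and p == lab)
        fn = sum(1 for g, p in zip(gold, pred) if g == lab and p != lab)
        out[lab] = ClassCounts(tp, fp, fn, n - tp - fp - fn)
    return out


def classification_report(
    gold: Sequence[Hashable], pred: Sequence[Hashable]
) -> dict:
    """Per-class PRF + support, plus micro and support-weighted overalls."""
    counts = confusion_counts(gold, pred)
    support = Counter(gold)
    per_class = {}
    for lab, c in counts.items():
        p, r, f = prf(c)
        per_class[str(lab)] = {
            "precision": p, "recall": r, "f1": f, "support": support[lab],
        }
    n = len(gold)
    tp_total = sum(c.true_positive for c in counts.values())
    micro = tp_total / n if n else math.nan  # = accuracy for single-label multiclass

    def _wavg(key: str) -> float:
        tot, wsum = 0, 0.0
        for lab, c in counts.items():
            m = per_class[str(lab)][key]
            if support[lab] and not math.isnan(m):
                wsum += support[lab] * m
                tot += support[lab]
        return wsum / tot if tot else math.nan

    return {
        "per_class": per_class,
        "overall_micro": {"precision": micro, "recall": micro, "f1": micro},
        "overall_weighted": {
            "precision": _wavg("precision"),
            "recall": _wavg("recall"),
            "f1": _wavg("f1"),
        },
        "n": n,
    }


def cohens_kappa(labels_a: Sequence[Hashable], labels_b: Sequence[Hashable]) -> float:
    """Unweighted Cohen's kappa between two raters' label sequences."""
    if len(labels_a) != len(labels_b) or not labels_a:
        raise ValueError("label lists must be non-empty and of equal length")
    n = len(labels_a)
    p_o = Fraction(sum(1 for a, b in zip(labels_a, labels_b) if a == b), n)
    ca, cb = Counter(labels_a), Counter(labels_b)
    p_e = sum(
        Fraction(ca[lab], n) * Fraction(cb[lab], n) for lab in set(ca) | set(cb)
    )
    if p_e == 1:
        logger.warning("both raters constant and equal; kappa = 1 by convention")
        return 1.0
    return float((p_o - p_e) / (1 - p_e))
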