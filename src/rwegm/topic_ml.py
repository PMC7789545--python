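"""Machine-learning topic classifier: bag-of-words + random forest.

Sentences (already normalized/masked) are vectorized as token counts and fed
to a random-forest classifier at one of two topic granularities: the full
seven topics, or four topics where the context topics (Information,
Evaluation, Order, Insurance) collapse into Information and the result topics
(Positive, Negative, VUS) stay separate.  Performance is estimated by
stratified ten-fold cross-validation with the vocabulary fitted on training
folds only; feature importance reports mean impurity decrease plus the number
of tree nodes splitting on each token.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.model_selection import StratifiedKFold

from . import eval_metrics
from .textprep import SentenceRecord

logger = logging.getLogger(__name__)

COARSE_MAP = {
    "Information": "Information",
    "Evaluation": "Information",
    "Order": "Information",
    "Insurance": "Information",
    "Positive": "Positive",
    "Negative": "Negative",
    "VUS": "VUS",
}


def to_coarse(labels: Sequence[str]) -> list[str]:
    """Collapse the seven topics to the four-topic granularity."""
    return [COARSE_MAP[l] for l in labels]


def _make_vectorizer() -> CountVectorizer:
    # tokens are already normalized; split on whitespace, no re-lowercasing
    return CountVectorizer(token_pattern=r"\S+", lowercase=False)


def vectorize(records: Sequence[SentenceRecord]):
    """Fit a token-count vocabulary and vectorize the corpus.

    Returns (X sparse matrix, fitted CountVectorizer).  Unseen tokens at
    prediction time are ignored by the fitted vocabulary.
    """
    texts = [r.normalized_text for r in records]
    vec = _make_vectorizer()
    try:
        X = vec.fit_transform(texts)
    except ValueError as exc:  # empty vocabulary
        raise ValueError("empty vocabulary: no usable tokens in corpus") from exc
    return X, vec


@dataclass
class CvReport:
    granularity: str
    n_folds: int
    seed: int
    per_class: dict
    overall_micro: dict
    overall_weighted: dict
    predictions: list[str] = field(repr=False, default_factory=list)
    feature_importance: list[tuple[str, float, int]] = field(
        repr=False, default_factory=list)

    def to_dict(self) -> dict:
        return {
            "granularity": self.granularity,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "per_class": self.per_class,
            "overall_micro": self.overall_micro,
            "overall_weighted": self.overall_weighted,
            "feature_importance": [
                {"token": t, "mean_impurity_decrease": imp, "n_nodes": nn}
                for t, imp, nn in self.feature_importance
            ],
        }


def _forest(seed: int, n_trees: int, max_features) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        random_state=seed,
        n_jobs=1,
    )


def crossvalidate(
    records: Sequence[SentenceRecord],
    labels: Sequence[str],
    granularity: str = "seven",
    n_folds: int = 10,
    seed: int = 13,
    n_trees: int = 500,
    max_features="sqrt",
    importance_top_n: int = 50,
) -> CvReport:
    """Stratified k-fold cross-validation of the bag-of-words forest.

    The report aggregates out-of-fold predictions (their count equals the
    dataset size) into per-class precision/recall/F1 with support, plus
    micro and support-weighted overall metrics; identical seeds give
    identical fold assignments, predictions and metrics.  Classes with fewer
    members than folds trigger a warning (stratification then degrades for
    those classes).  Feature importance comes from a forest fitted on the
    full corpus.
    """
    if granularity not in ("four", "seven"):
        raise ValueError("granularity must be 'four' or 'seven'")
    y = list(labels) if granularity == "seven" else to_coarse(labels)
    if len(records) != len(y):
        raise ValueError("records and labels must align")
    if len(records) < n_folds:
        raise ValueError("need at least n_folds labeled examples")
    texts = np.array([r.normalized_text for r in records], dtype=object)
    y_arr = np.array(y, dtype=object)
    classes, counts = np.unique(y_arr, return_counts=True)
    small = classes[counts < n_folds]
    if len(small):
        logger.warning(
            "classes %s have fewer members than n_folds=%d; stratification "
            "degrades for them", list(small), n_folds)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    preds = np.empty(len(y_arr), dtype=object)
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="The least populated class", category=UserWarning)
        for fold_i, (tr, te) in enumerate(skf.split(texts, y_arr)):
            vec = _make_vectorizer()
            X_tr = vec.fit_transform(texts[tr])
            X_te = vec.transform(texts[te])
            clf = _forest(seed + fold_i, n_trees, max_features)
            clf.fit(X_tr, y_arr[tr])
            preds[te] = clf.predict(X_te)

    report = eval_metrics.classification_report(list(y_arr), list(preds))

    vec = _make_vectorizer()
    X = vec.fit_transform(texts)
    clf = _forest(seed, n_trees, max_features)
    clf.fit(X, y_arr)
    importance = feature_importance(clf, vec.get_feature_names_out())[:importance_top_n]

    return CvReport(
        granularity=granularity,
        n_folds=n_folds,
        seed=seed,
        per_class=report["per_class"],
        overall_micro=report["overall_micro"],
        overall_weighted=report["overall_weighted"],
        predictions=list(preds),
        feature_importance=importance,
    )


def feature_importance(
    forest: RandomForestClassifier, feature_names: Sequence[str]
) -> list[tuple[str, float, int]]:
    """Tokens ranked by mean impurity decrease, with per-token node counts.

    The node count is the number of internal nodes, across all trees, that
    split on the token; constant features have importance 0.
    """
    imp = forest.feature_importances_
    n_nodes = np.zeros(len(feature_names), dtype=int)
    for est in forest.estimators_:
        feats = est.tree_.feature
        used = feats[feats >= 0]
        np.add.at(n_nodes, used, 1)
    ranked = sorted(
        zip(feature_names, imp.tolist(), n_nodes.tolist()),
        key=lambda t: (-t[1], t[0]),
    )
    return [(str(t), float(i), int(n)) for t, i, n in ranked]
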