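"""Bag-of-words feature construction and selection.

Each note is represented by TF-IDF weights over all 1-, 2- and 3-grams of
its lowercased, punctuation-stripped tokens; chi-square feature selection
then keeps the k n-grams (default 100) most associated with the note label.
Down-sampling discards majority-class notes at random until the classes are
balanced, which trades PPV for sensitivity in the trained models.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.feature_selection import chi2 as sk_chi2

from ..context import Note

__all__ = [
    "build_ngrams",
    "FeatureMatrix",
    "TfidfFeaturizer",
    "fit_tfidf",
    "chi2_select",
    "downsample",
]

log = logging.getLogger(__name__)

_TOKEN = re.compile(r"[a-z0-9]+")


def build_ngrams(text: str, n_range: Tuple[int, int] = (1, 3)) -> List[str]:
    """Contiguous word n-grams after lowercasing and punctuation stripping."""
    tokens = _TOKEN.findall(text.lower())
    lo, hi = n_range
    grams: List[str] = []
    for n in range(lo, hi + 1):
        grams.extend(
            " ".join(tokens[i : i + n]) for i in range(len(tokens) - n + 1)
        )
    return grams


@dataclass
class FeatureMatrix:
    """TF-IDF note-by-feature matrix with its ordered vocabulary."""

    values: sp.csr_matrix
    vocabulary: List[str]
    note_ids: List[str]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    def restrict(self, columns: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            values=sp.csr_matrix(self.values[:, columns]),
            vocabulary=[self.vocabulary[j] for j in columns],
            note_ids=list(self.note_ids),
        )


class TfidfFeaturizer:
    """Fitted TF-IDF vectorizer over 1-3-gram vocabulary.

    Weights use raw term counts, smoothed idf ``ln((1+N)/(1+df)) + 1`` and
    per-note L2 normalization; transforming unseen notes drops
    out-of-vocabulary n-grams.
    """

    def __init__(self, n_range: Tuple[int, int] = (1, 3)):
        self.n_range = n_range
        self._vec = TfidfVectorizer(
            analyzer=lambda text: build_ngrams(text, n_range),
            norm="l2",
            smooth_idf=True,
            sublinear_tf=False,
        )

    def fit_transform(self, corpus: Sequence[Note]) -> FeatureMatrix:
        if not corpus or all(not n.text.strip() for n in corpus):
            raise ValueError("corpus must contain at least one non-empty note")
        X = self._vec.fit_transform([n.text for n in corpus])
        return FeatureMatrix(
            values=sp.csr_matrix(X),
            vocabulary=list(self._vec.get_feature_names_out()),
            note_ids=[n.note_id for n in corpus],
        )

    def transform(self, corpus: Sequence[Note]) -> FeatureMatrix:
        X = self._vec.transform([n.text for n in corpus])
        return FeatureMatrix(
            values=sp.csr_matrix(X),
            vocabulary=list(self._vec.get_feature_names_out()),
            note_ids=[n.note_id for n in corpus],
        )

    @property
    def idf(self) -> np.ndarray:
        return self._vec.idf_

    @property
    def vocabulary(self) -> List[str]:
        return list(self._vec.get_feature_names_out())


def fit_tfidf(
    corpus: Sequence[Note], n_range: Tuple[int, int] = (1, 3)
) -> Tuple[FeatureMatrix, TfidfFeaturizer]:
    """Fit the TF-IDF vocabulary on a corpus and return matrix + featurizer."""
    feat = TfidfFeaturizer(n_range)
    return feat.fit_transform(corpus), feat


def _chi2_binary(X: sp.csr_matrix, g: np.ndarray) -> np.ndarray:
    """Per-feature 2x2 chi-square on presence/absence counts (no correction)."""
    present = (X > 0).astype(np.float64)
    n = g.size
    n_pos = float(g.sum())
    with_pos = np.asarray(present[g == 1].sum(axis=0)).ravel()
    with_any = np.asarray(present.sum(axis=0)).ravel()
    scores = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        a = with_pos[j]                # present, positive class
        b = with_any[j] - a            # present, negative class
        c = n_pos - a                  # absent, positive class
        d = n - n_pos - b              # absent, negative class
        row1, row2 = a + b, c + d
        col1, col2 = a + c, b + d
        if 0 in (row1, row2, col1, col2):
            continue
        scores[j] = n * (a * d - b * c) ** 2 / (row1 * row2 * col1 * col2)
    return scores


def chi2_select(
    matrix: FeatureMatrix,
    gold: Sequence[int],
    k: int = 100,
    binary: bool = False,
    return_scores: bool = False,
):
    """Keep the k features most associated with the label by chi-square.

    By default scores are the chi-square statistic between per-class
    feature mass (summed TF-IDF weight) and the binary label; with
    ``binary=True`` each feature is reduced to presence/absence and scored
    by the full 2x2 contingency chi-square.  Boundary ties are broken by
    vocabulary order.  When ``k`` exceeds the vocabulary size all features
    are kept and a warning is logged.  Returns the restricted matrix and
    the selected column indices (plus the full score vector when
    ``return_scores``).
    """
    g = np.asarray(gold, dtype=int)
    if len(np.unique(g)) < 2:
        raise ValueError("chi-square selection requires both classes")
    if g.size != matrix.shape[0]:
        raise ValueError("label length does not match matrix rows")
    if binary:
        scores = _chi2_binary(matrix.values, g)
    else:
        scores, _ = sk_chi2(matrix.values, g)
    scores = np.nan_to_num(scores, nan=0.0)
    n_feat = matrix.shape[1]
    if k > n_feat:
        log.warning(
            "requested k=%d exceeds vocabulary size %d; keeping all features",
            k,
            n_feat,
        )
        k = n_feat
    # stable sort on (-score, column index) implements vocabulary-order ties
    order = np.lexsort((np.arange(n_feat), -scores))
    cols = np.sort(order[:k])
    selected = matrix.restrict(cols)
    if return_scores:
        return selected, cols, scores
    return selected, cols


def downsample(gold: Sequence[int], seed: int) -> np.ndarray:
    """Balanced index subset: all minority notes plus a random majority sample.

    Deterministic for a given seed; returned indices are sorted.
    """
    g = np.asarray(gold, dtype=int)
    classes, counts = np.unique(g, return_counts=True)
    if len(classes) < 2:
        raise ValueError("down-sampling requires both classes")
    if counts[0] == counts[1]:
        return np.arange(g.size)
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    keep_major = rng.choice(np.flatnonzero(g == majority), size=n_min, replace=False)
    idx = np.concatenate([np.flatnonzero(g == minority), keep_major])
    return np.sort(idx)
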