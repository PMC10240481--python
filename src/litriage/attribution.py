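"""Integrated-gradient attributions and word-impact aggregation.

Integrated gradients assign each input feature its contribution to a
differentiable scorer's output relative to a baseline input, by averaging
the gradient along the straight-line path from baseline to input
(midpoint Riemann approximation) and scaling by the input-baseline
difference.  The downstream aggregation is model-agnostic: sub-word
scores are averaged into surface-word scores, words are lemmatized and
lowercased so inflectional variants pool their scores, and the report
ranks the positive-impact lemmas seen at least ``min_occurrences`` times.

For the packaged count-feature baseline the scorer is the (analytic)
softmax probability of a target label group, so features are already
whole words; token-score files produced by external models (where words
split into marked continuation sub-words) enter through the same
aggregation path.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Protocol, Sequence

import numpy as np
import pandas as pd

from .classify import BaselineClassifier, predict_label
from .corpus import Corpus
from .taxonomy import SUBCLASS

__all__ = [
    "AttributionError",
    "DifferentiableScorer",
    "LinearScorer",
    "LogisticScorer",
    "SoftmaxGroupScorer",
    "integrated_gradients",
    "TokenAttribution",
    "word_scores_from_subwords",
    "WordImpact",
    "default_lemmatize",
    "aggregate_lemma_scores",
    "top_impact_words",
    "read_token_attributions",
    "write_token_attributions",
    "subclass_word_impacts",
]


class AttributionError(ValueError):
    """Attribution input violates its contract."""


class DifferentiableScorer(Protocol):
    """A map from a feature vector to a scalar score, with gradients."""

    def value(self, x: np.ndarray) -> float: ...

    def gradient(self, x: np.ndarray) -> np.ndarray: ...


@dataclass
class LinearScorer:
    """score = w . x + b (gradient constant in x)."""

    w: np.ndarray
    b: float = 0.0

    def value(self, x: np.ndarray) -> float:
        return float(self.w @ x + self.b)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self.w, dtype=float)


@dataclass
class LogisticScorer:
    """score = sigmoid(w . x + b)."""

    w: np.ndarray
    b: float = 0.0

    def value(self, x: np.ndarray) -> float:
        return float(1.0 / (1.0 + np.exp(-(self.w @ x + self.b))))

    def gradient(self, x: np.ndarray) -> np.ndarray:
        p = self.value(x)
        return p * (1.0 - p) * np.asarray(self.w, dtype=float)


class SoftmaxGroupScorer:
    """Softmax probability mass of a group of classes of a linear model.

    ``score(x) = sum_{t in targets} softmax(W x + b)_t`` — e.g. the
    rolled-up subclass probability of a multinomial logistic classifier.
    The gradient is analytic:
    ``d score / dx = sum_t p_t W_t  -  score * sum_c p_c W_c``.
    """

    def __init__(self, weights: np.ndarray, intercepts: np.ndarray, targets: Sequence[int]):
        self.weights = np.asarray(weights, dtype=float)  # (C, d)
        self.intercepts = np.asarray(intercepts, dtype=float)  # (C,)
        self.targets = np.asarray(list(targets), dtype=int)

    def _proba(self, x: np.ndarray) -> np.ndarray:
        z = self.weights @ x + self.intercepts
        z -= z.max()
        e = np.exp(z)
        return e / e.sum()

    def value(self, x: np.ndarray) -> float:
        return float(self._proba(x)[self.targets].sum())

    def gradient(self, x: np.ndarray) -> np.ndarray:
        p = self._proba(x)
        mean_w = p @ self.weights
        score = p[self.targets].sum()
        return p[self.targets] @ self.weights[self.targets] - score * mean_w


def integrated_gradients(
    scorer: DifferentiableScorer,
    x: Sequence[float],
    baseline: Sequence[float] | None = None,
    steps: int = 50,
) -> np.ndarray:
    """Path-integral attribution of ``scorer`` at ``x`` against ``baseline``.

    ``attribution_i = (x_i - baseline_i) * mean_k grad_i(baseline +
    alpha_k (x - baseline))`` with midpoints ``alpha_k = (k + 1/2)/steps``.
    The default baseline is the all-zero vector (an empty document for
    count features).  Attributions satisfy the completeness axiom —
    summing to ``scorer(x) - scorer(baseline)`` — up to the Riemann
    discretization error, and are exact for linear scorers.
    """
    x = np.asarray(x, dtype=float)
    baseline = np.zeros_like(x) if baseline is None else np.asarray(baseline, dtype=float)
    if x.shape != baseline.shape:
        raise AttributionError("x and baseline must have the same shape")
    if steps < 1:
        raise AttributionError("steps must be >= 1")
    diff = x - baseline
    total = np.zeros_like(x)
    for k in range(steps):
        alpha = (k + 0.5) / steps
        g = np.asarray(scorer.gradient(baseline + alpha * diff), dtype=float)
        if not np.all(np.isfinite(g)):
            raise AttributionError(f"non-finite gradient at path step {k}")
        total += g
    return diff * total / steps


# ---------------------------------------------------------------------- #
# token -> word -> lemma aggregation


@dataclass(frozen=True)
class TokenAttribution:
    """One (sub-word) token's signed impact score within a document."""

    doc_id: str
    index: int
    token: str
    is_continuation: bool
    score: float


def word_scores_from_subwords(
    tokens: Iterable[TokenAttribution | tuple],
) -> list[tuple[str, float]]:
    """Merge consecutive continuation sub-words into surface words.

    Accepts :class:`TokenAttribution` rows or ``(token, is_continuation,
    score)`` tuples in document order; a continuation marker (leading
    ``#`` stripped) extends the preceding head token.  Each word's score
    is the arithmetic mean of its constituent sub-word scores.
    """
    words: list[tuple[str, float]] = []
    current: list[str] = []
    scores: list[float] = []
    for tok in tokens:
        if isinstance(tok, TokenAttribution):
            text, cont, score = tok.token, tok.is_continuation, tok.score
        else:
            text, cont, score = tok
        if cont:
            if not current:
                raise AttributionError(f"continuation token {text!r} has no preceding head")
            current.append(text.lstrip("#"))
            scores.append(float(score))
        else:
            if current:
                words.append(("".join(current), float(np.mean(scores))))
            current, scores = [text], [float(score)]
    if current:
        words.append(("".join(current), float(np.mean(scores))))
    return words


@dataclass(frozen=True)
class WordImpact:
    """Pooled impact of one lemma across the analyzed document set."""

    lemma: str
    mean_score: float
    occurrences: int


_IRREGULAR = {
    "studies": "study",
    "analyses": "analysis",
    "hypotheses": "hypothesis",
    "viruses": "virus",
    "data": "data",
}


def default_lemmatize(word: str) -> str:
    """Small rule lemmatizer: lowercase and strip common plural suffixes.

    Handles the regular English plural patterns (``simulations`` →
    ``simulation``, ``studies`` → ``study``, ``boxes`` → ``box``) plus a
    short irregular list.  Deterministic; pluggable wherever a
    lemmatizer is accepted.
    """
    w = word.lower()
    if w in _IRREGULAR:
        return _IRREGULAR[w]
    if len(w) > 4 and w.endswith("ies"):
        return w[:-3] + "y"
    if len(w) > 3 and w.endswith("es") and w[:-2].endswith(("s", "x", "z", "ch", "sh")):
        return w[:-2]
    if len(w) > 3 and w.endswith("s") and not w.endswith(("ss", "us", "is")):
        return w[:-1]
    return w


def aggregate_lemma_scores(
    word_scores_by_doc: Iterable[Iterable[tuple[str, float]]],
    lemmatizer: Callable[[str], str] = default_lemmatize,
) -> list[WordImpact]:
    """Pool per-document word scores by lowercased lemma.

    ``word_scores_by_doc`` is one ``(word, score)`` list per document;
    the result carries, per lemma, the arithmetic mean over all its
    occurrences across all documents, and the occurrence count.
    """
    pooled: dict[str, list[float]] = {}
    for doc in word_scores_by_doc:
        for word, score in doc:
            lemma = lemmatizer(word).lower()
            pooled.setdefault(lemma, []).append(float(score))
    return [
        WordImpact(lemma=lemma, mean_score=float(np.mean(scores)), occurrences=len(scores))
        for lemma, scores in pooled.items()
    ]


def top_impact_words(
    impacts: Iterable[WordImpact], k: int = 20, min_occurrences: int = 5
) -> list[WordImpact]:
    """The k highest positive-impact lemmas with enough occurrences.

    Lemmas below ``min_occurrences`` or with non-positive mean score are
    dropped; survivors are ranked by mean score descending (ties
    lexicographic by lemma) and truncated to ``k``.
    """
    kept = [
        w for w in impacts if w.occurrences >= min_occurrences and w.mean_score > 0
    ]
    kept.sort(key=lambda w: (-w.mean_score, w.lemma))
    return kept[:k]


# ---------------------------------------------------------------------- #
# file formats


_TOKEN_COLUMNS = ["doc_id", "token_index", "token", "is_continuation", "score"]


def write_token_attributions(rows: Iterable[TokenAttribution], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "doc_id": r.doc_id,
                "token_index": r.index,
                "token": r.token,
                "is_continuation": int(r.is_continuation),
                "score": r.score,
            }
            for r in rows
        ],
        columns=_TOKEN_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_token_attributions(path: str | Path) -> list[TokenAttribution]:
    df = pd.read_csv(path, sep="\t", dtype={"doc_id": str, "token": str})
    missing = [c for c in _TOKEN_COLUMNS if c not in df.columns]
    if missing:
        raise AttributionError(f"{path}: missing column(s) {missing}")
    rows = [
        TokenAttribution(
            doc_id=r.doc_id,
            index=int(r.token_index),
            token=r.token,
            is_continuation=bool(r.is_continuation),
            score=float(r.score),
        )
        for r in df.itertuples()
    ]
    for doc_id, grp in df.groupby("doc_id"):
        if not grp["token_index"].is_monotonic_increasing:
            raise AttributionError(f"{path}: token indices not increasing for doc {doc_id!r}")
    return rows


def impacts_to_frame(impacts: Sequence[WordImpact]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"lemma": w.lemma, "mean_score": w.mean_score, "occurrences": w.occurrences, "rank": i + 1}
            for i, w in enumerate(impacts)
        ],
        columns=["lemma", "mean_score", "occurrences", "rank"],
    )


# ---------------------------------------------------------------------- #
# end-to-end helper for the baseline classifier


def subclass_word_impacts(
    model: BaselineClassifier,
    corpus: Corpus,
    subclass_id: str | None = None,
    steps: int = 50,
    use_true_label: bool = False,
    lemmatizer: Callable[[str], str] = default_lemmatize,
) -> dict[str, list[WordImpact]]:
    """Word-impact aggregation per subclass for the count-feature baseline.

    Every document is attributed toward a subclass: its *predicted*
    subclass by default (``use_true_label`` switches to the annotated
    one), or a fixed ``subclass_id`` when given.  The scorer is the
    analytic softmax mass of the subclass's leaves against an all-zero
    (empty-document) baseline; per-feature attributions map directly to
    vocabulary words, which then pool by lemma.  Returns one
    :class:`WordImpact` list per subclass.
    """
    if model._clf is None:
        raise AttributionError("attribution requires a fitted multi-class baseline")
    taxonomy = model.taxonomy
    vectorizer = model._vectorizer
    vocab = vectorizer.get_feature_names_out()
    clf = model._clf
    classes = list(clf.classes_)
    probs = model.predict_proba(corpus)
    if subclass_id is not None:
        doc_subclass = [taxonomy.resolve(subclass_id)] * len(corpus)
    elif use_true_label:
        doc_subclass = [taxonomy.ancestor(r.label, SUBCLASS) for r in corpus]
    else:
        doc_subclass = [
            taxonomy.ancestor(leaf, SUBCLASS)
            for leaf in predict_label(probs, taxonomy, "sub-subclass")
        ]
    scorers = {}
    for sub in set(doc_subclass):
        targets = [classes.index(l) for l in taxonomy.leaves_under(sub) if l in classes]
        if not targets:
            raise AttributionError(f"no trained leaf under subclass {sub!r}")
        scorers[sub] = SoftmaxGroupScorer(clf.coef_, clf.intercept_, targets)
    from .corpus import compose_input_text

    x_all = vectorizer.transform([compose_input_text(r) for r in corpus]).toarray()
    per_subclass_docs: dict[str, list[list[tuple[str, float]]]] = {}
    for i, sub in enumerate(doc_subclass):
        attr = integrated_gradients(scorers[sub], x_all[i], steps=steps)
        present = np.nonzero(x_all[i])[0]
        words = [(vocab[j], float(attr[j])) for j in present]
        per_subclass_docs.setdefault(sub, []).append(words)
    return {
        sub: aggregate_lemma_scores(docs, lemmatizer=lemmatizer)
        for sub, docs in per_subclass_docs.items()
    }
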