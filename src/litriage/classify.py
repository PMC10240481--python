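"""Base-classifier contract and the count-feature baseline classifier.

Any model that maps a preprocessed corpus to a row-stochastic documents ×
leaves probability matrix can participate in the ensembles; the contract
is the :class:`ProbabilityMatrix` it must produce.  The packaged baseline
is a multinomial logistic regression over lowercased word-count features
with its regularization strength selected on a dev set by micro F1 — a
fast, deterministic model that learns class-conditional lexical signal.
External models (e.g. fine-tuned transformers) join by writing their
probability matrices to the delimited text format read here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression

from .corpus import Corpus, compose_input_text
from .taxonomy import Taxonomy

__all__ = [
    "ProbabilityMatrix",
    "MatrixValidationError",
    "BaselineClassifier",
    "fit_baseline",
    "predict_label",
]

ROW_SUM_ATOL = 1e-6
_PERSIST_VERSION = 1


class MatrixValidationError(ValueError):
    """A probability matrix violates its invariants."""


@dataclass
class ProbabilityMatrix:
    """Documents × leaf-labels matrix of predicted probabilities.

    Each row is a distribution over ``leaf_order`` (nonnegative, summing
    to 1 within ``1e-6``); columns align with the active taxonomy's leaf
    order.
    """

    doc_ids: list[str]
    leaf_order: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.doc_ids = list(self.doc_ids)
        self.leaf_order = list(self.leaf_order)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.doc_ids), len(self.leaf_order)):
            raise MatrixValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.doc_ids)} docs x {len(self.leaf_order)} leaves"
            )
        if len(set(self.doc_ids)) != len(self.doc_ids):
            raise MatrixValidationError("duplicate doc_ids")
        if self.values.size:
            if np.any(self.values < 0):
                raise MatrixValidationError("negative probability entries")
            bad = np.where(np.abs(self.values.sum(axis=1) - 1.0) > ROW_SUM_ATOL)[0]
            if len(bad):
                raise MatrixValidationError(
                    f"row(s) {bad[:5].tolist()} do not sum to 1 within {ROW_SUM_ATOL}"
                )

    @property
    def n_docs(self) -> int:
        return len(self.doc_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.doc_ids, columns=self.leaf_order)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "doc_id"
        df.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def read_tsv(cls, path: str | Path, taxonomy: Taxonomy | None = None) -> "ProbabilityMatrix":
        """Read a matrix; with a taxonomy, the header must equal its leaf order."""
        df = pd.read_csv(path, sep="\t", index_col="doc_id")
        if taxonomy is not None and list(df.columns) != list(taxonomy.leaf_order):
            raise MatrixValidationError(
                f"{path}: column header does not match taxonomy leaf order"
            )
        return cls(
            doc_ids=[str(d) for d in df.index],
            leaf_order=list(df.columns),
            values=df.to_numpy(dtype=float),
        )


def predict_label(probs: ProbabilityMatrix, taxonomy: Taxonomy, level: str) -> list[str]:
    """Per-document predicted label at ``level``.

    The leaf distribution is rolled up to ``level`` and the label with the
    highest probability is returned; exact ties go to the earlier label in
    canonical order (``argmax`` keeps the first maximum).
    """
    rolled = taxonomy.roll_up_matrix(probs.values, level)
    labels = taxonomy.labels_at(level)
    return [labels[i] for i in np.argmax(rolled, axis=1)]


class BaselineClassifier:
    """Multinomial logistic regression over lowercased token counts.

    Tokens are whitespace/punctuation-delimited word tokens; tokens seen
    fewer than ``min_token_count`` times in training are dropped.  The
    inverse-regularization strength is chosen from ``c_grid`` by dev-set
    micro F1 (identical to accuracy in this single-label setting).
    Training is deterministic given the seed.
    """

    def __init__(
        self,
        taxonomy: Taxonomy,
        model_name: str = "count-logit",
        c_grid: Sequence[float] = (0.001, 0.01, 0.1, 1.0, 10.0),
        min_token_count: int = 1,
        seed: int = 0,
    ):
        self.taxonomy = taxonomy
        self.model_name = model_name
        self.c_grid = tuple(c_grid)
        self.min_token_count = int(min_token_count)
        self.seed = int(seed)
        self._vectorizer: CountVectorizer | None = None
        self._clf: LogisticRegression | None = None
        self._single_class: str | None = None
        self.best_c_: float | None = None
        self.dev_score_: float | None = None

    # ------------------------------------------------------------------ #

    def _texts(self, corpus: Corpus) -> list[str]:
        return [compose_input_text(r) for r in corpus]

    def fit(self, train: Corpus, dev: Corpus) -> "BaselineClassifier":
        labels = [r.label for r in train]
        if not len(train):
            raise ValueError("training corpus is empty")
        if any(l is None for l in labels):
            raise ValueError("training corpus must be fully labeled")
        absent = set(self.taxonomy.leaf_order) - set(labels)
        if absent:
            warnings.warn(
                f"{len(absent)} leaf label(s) absent from training data; "
                "the model can never predict them",
                stacklevel=2,
            )
        self._vectorizer = CountVectorizer(
            lowercase=True,
            token_pattern=r"(?u)\b\w+\b",
            min_df=self.min_token_count,
        )
        x_train = self._vectorizer.fit_transform(self._texts(train))
        classes = sorted(set(labels))
        if len(classes) == 1:
            # degenerate corpus: constant predictor, still row-stochastic
            self._single_class = classes[0]
            self.best_c_ = None
            self.dev_score_ = float(
                np.mean([r.label == classes[0] for r in dev]) if len(dev) else 1.0
            )
            return self
        x_dev = self._vectorizer.transform(self._texts(dev))
        y_dev = [r.label for r in dev]
        best = None
        for c in self.c_grid:
            clf = LogisticRegression(
                C=c, max_iter=2000, random_state=self.seed, solver="lbfgs"
            )
            clf.fit(x_train, labels)
            score = float(np.mean(clf.predict(x_dev) == np.array(y_dev))) if len(dev) else 0.0
            if best is None or score > best[0]:
                best = (score, c, clf)
        self.dev_score_, self.best_c_, self._clf = best
        return self

    @property
    def is_fitted(self) -> bool:
        return self._vectorizer is not None

    def predict_proba(self, corpus: Corpus) -> ProbabilityMatrix:
        """Probability matrix over the full taxonomy leaf order.

        Leaves absent from training receive probability 0; rows remain
        valid distributions.  An empty corpus yields an empty matrix.
        """
        if not self.is_fitted:
            raise ValueError("model is not fitted")
        leaf_order = list(self.taxonomy.leaf_order)
        if not len(corpus):
            return ProbabilityMatrix([], leaf_order, np.zeros((0, len(leaf_order))))
        n = len(corpus)
        out = np.zeros((n, len(leaf_order)))
        if self._single_class is not None:
            out[:, leaf_order.index(self._single_class)] = 1.0
        else:
            x = self._vectorizer.transform(self._texts(corpus))
            proba = self._clf.predict_proba(x)
            col = {leaf: j for j, leaf in enumerate(leaf_order)}
            for i, cls in enumerate(self._clf.classes_):
                out[:, col[cls]] = proba[:, i]
        return ProbabilityMatrix(corpus.doc_ids, leaf_order, out)

    # ------------------------------------------------------------------ #
    # persistence

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "format_version": _PERSIST_VERSION,
                "taxonomy_fingerprint": self.taxonomy.fingerprint,
                "model_name": self.model_name,
                "c_grid": self.c_grid,
                "min_token_count": self.min_token_count,
                "seed": self.seed,
                "vectorizer": self._vectorizer,
                "clf": self._clf,
                "single_class": self._single_class,
                "best_c": self.best_c_,
                "dev_score": self.dev_score_,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path, taxonomy: Taxonomy) -> "BaselineClassifier":
        """Load a persisted model; refuses to load under a mismatched taxonomy."""
        blob = joblib.load(path)
        if blob.get("format_version") != _PERSIST_VERSION:
            raise ValueError(f"unsupported model archive version {blob.get('format_version')!r}")
        if blob["taxonomy_fingerprint"] != taxonomy.fingerprint:
            raise ValueError(
                "model was trained under a different taxonomy "
                f"(fingerprint {blob['taxonomy_fingerprint']} != {taxonomy.fingerprint})"
            )
        model = cls(
            taxonomy,
            model_name=blob["model_name"],
            c_grid=blob["c_grid"],
            min_token_count=blob["min_token_count"],
            seed=blob["seed"],
        )
        model._vectorizer = blob["vectorizer"]
        model._clf = blob["clf"]
        model._single_class = blob["single_class"]
        model.best_c_ = blob["best_c"]
        model.dev_score_ = blob["dev_score"]
        return model


def fit_baseline(
    train: Corpus,
    dev: Corpus,
    taxonomy: Taxonomy,
    c_grid: Sequence[float] = (0.001, 0.01, 0.1, 1.0, 10.0),
    min_token_count: int = 1,
    seed: int = 0,
    model_name: str = "count-logit",
) -> BaselineClassifier:
    """Fit the baseline classifier (functional convenience wrapper)."""
    model = BaselineClassifier(
        taxonomy,
        model_name=model_name,
        c_grid=c_grid,
        min_token_count=min_token_count,
        seed=seed,
    )
    return model.fit(train, dev)
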