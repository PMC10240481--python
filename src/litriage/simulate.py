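"""Synthetic corpora and simulated multi-model predictions.

The corpus generator emulates the structure of a living-evidence
annotation snapshot: heavily imbalanced leaf labels (default frequency
profile = the published COAP per-leaf counts, 0.5%–27.6%), three
free-text fields per record drawn from a shared background vocabulary,
and class-conditional lexical signal — each leaf owns a small signature
vocabulary from which content tokens are drawn with probability
``signal_strength``.  At signal 0 the text carries no label information;
near 1 the task is essentially separable, which gives the classifier and
attribution modules a learnable, verifiable target.

The prediction simulator stands in for an ensemble of fine-tuned models:
each member's modal label equals the truth with its configured accuracy;
errors preferentially land on a same-subclass leaf (3:1 over
cross-subclass), reproducing the intra-subclass confusion structure of
real taxonomies, and an ``agreement`` knob correlates the members' error
events through a shared latent "hard document" draw.  Row sharpness
around the modal label is a single concentration parameter, which
controls how often per-vote probability thresholds trigger abstention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classify import ProbabilityMatrix
from .corpus import Corpus, DocumentRecord
from .ensemble import EnsembleInput
from .taxonomy import SUBCLASS, Taxonomy, coap_leaf_counts, default_taxonomy

__all__ = [
    "CorpusGeneratorConfig",
    "PredictionSimulatorConfig",
    "generate_corpus",
    "signature_token",
    "signature_lemmas",
    "simulate_predictions",
]

DEFAULT_SOURCES = ("PubMed", "Embase", "medRxiv", "bioRxiv")


@dataclass
class CorpusGeneratorConfig:
    """Knobs of the synthetic corpus generator.

    ``leaf_proportions`` defaults to the published COAP snapshot profile;
    ``signal_strength`` is the probability that a content token comes
    from the document's leaf signature vocabulary rather than the shared
    background.  Token counts per field are inclusive ranges.
    """

    taxonomy: Taxonomy = field(default_factory=default_taxonomy)
    n_docs: int = 1000
    leaf_proportions: Sequence[float] | None = None
    signature_tokens_per_leaf: int = 5
    signal_strength: float = 0.8
    background_vocab_size: int = 500
    title_tokens: tuple[int, int] = (4, 10)
    abstract_tokens: tuple[int, int] = (40, 80)
    source_set: Sequence[str] = DEFAULT_SOURCES
    seed: int = 0

    def resolved_proportions(self) -> np.ndarray:
        if self.leaf_proportions is None:
            counts = coap_leaf_counts()
            if list(counts.index) != list(self.taxonomy.leaf_order):
                raise ValueError(
                    "default proportions only apply to the default taxonomy; "
                    "pass leaf_proportions explicitly"
                )
            p = counts.to_numpy(dtype=float)
        else:
            p = np.asarray(self.leaf_proportions, dtype=float)
            if p.shape != (self.taxonomy.n_leaves,):
                raise ValueError("leaf_proportions length does not match taxonomy")
        if not len(p) or p.sum() <= 0 or np.any(p < 0):
            raise ValueError("leaf proportions must be nonnegative and sum to > 0")
        return p / p.sum()


def signature_token(leaf_index: int, j: int) -> str:
    """The j-th signature token of leaf ``leaf_index`` (deterministic)."""
    return f"sig{leaf_index:02d}w{j}"


def signature_lemmas(config: CorpusGeneratorConfig, leaf_id: str) -> list[str]:
    """Signature vocabulary planted for ``leaf_id`` (already lemma-shaped)."""
    li = list(config.taxonomy.leaf_order).index(leaf_id)
    return [signature_token(li, j) for j in range(config.signature_tokens_per_leaf)]


def generate_corpus(config: CorpusGeneratorConfig) -> Corpus:
    """Labeled synthetic corpus with class-conditional lexical signal."""
    if not 0.0 <= config.signal_strength <= 1.0:
        raise ValueError("signal_strength must lie in [0, 1]")
    if config.n_docs < 1:
        raise ValueError("n_docs must be positive")
    rng = np.random.default_rng(config.seed)
    tax = config.taxonomy
    props = config.resolved_proportions()
    background = [f"bg{i:04d}" for i in range(config.background_vocab_size)]
    signatures = [
        [signature_token(li, j) for j in range(config.signature_tokens_per_leaf)]
        for li in range(tax.n_leaves)
    ]
    leaf_idx = rng.choice(tax.n_leaves, size=config.n_docs, p=props)

    def field_text(li: int, lo: int, hi: int) -> str:
        n_tok = int(rng.integers(lo, hi + 1))
        tokens = []
        for _ in range(n_tok):
            if rng.random() < config.signal_strength:
                tokens.append(signatures[li][int(rng.integers(len(signatures[li])))])
            else:
                tokens.append(background[int(rng.integers(len(background)))])
        return " ".join(tokens)

    records = []
    for i, li in enumerate(leaf_idx):
        records.append(
            DocumentRecord(
                doc_id=f"doc{i:05d}",
                title=field_text(li, *config.title_tokens),
                abstract=field_text(li, *config.abstract_tokens),
                source=str(config.source_set[int(rng.integers(len(config.source_set)))]),
                label=tax.leaf_order[li],
            )
        )
    return Corpus(records, taxonomy=tax)


# ---------------------------------------------------------------------- #
# prediction simulator


@dataclass
class PredictionSimulatorConfig:
    """Knobs of the multi-model prediction simulator.

    ``per_model_accuracy`` may be a scalar (shared) or one value per
    model.  ``agreement`` in [0, 1] correlates error events across
    models through a shared latent draw: at 0 errors are independent, at
    1 (with equal accuracies) all models err on exactly the same
    documents.  ``concentration`` is the Gamma shape of the modal label's
    probability mass; larger values sharpen rows toward one-hot.
    ``same_subclass_weight`` is the preference for confusing a leaf with
    another leaf of the same subclass over a cross-subclass leaf.
    """

    n_models: int = 5
    per_model_accuracy: float | Sequence[float] = 0.8
    agreement: float = 0.0
    concentration: float = 20.0
    same_subclass_weight: float = 3.0
    seed: int = 0

    def resolved_accuracies(self) -> np.ndarray:
        acc = np.asarray(self.per_model_accuracy, dtype=float)
        if acc.ndim == 0:
            acc = np.repeat(acc, self.n_models)
        if acc.shape != (self.n_models,):
            raise ValueError("per_model_accuracy length does not match n_models")
        if np.any(acc <= 0) or np.any(acc > 1):
            raise ValueError("per-model accuracies must lie in (0, 1]")
        return acc


def _confusion_weights(taxonomy: Taxonomy, same_subclass_weight: float) -> np.ndarray:
    """Row t: sampling weights of the wrong label given true leaf t."""
    n = taxonomy.n_leaves
    sub = [taxonomy.ancestor(l, SUBCLASS) for l in taxonomy.leaf_order]
    w = np.ones((n, n))
    for t in range(n):
        for j in range(n):
            if sub[j] == sub[t]:
                w[t, j] = same_subclass_weight
        w[t, t] = 0.0
        w[t] /= w[t].sum()
    return w


def simulate_predictions(
    truth: Sequence[str],
    taxonomy: Taxonomy,
    config: PredictionSimulatorConfig,
) -> EnsembleInput:
    """Simulated per-model probability matrices for the given true leaves.

    Each model/document pair draws a modal label — the truth with the
    model's accuracy, otherwise a confusable leaf — and a row peaked at
    that label whose argmax is guaranteed to be the modal label, so each
    member's empirical top-1 accuracy recovers its configured accuracy.
    """
    if not 0.0 <= config.agreement <= 1.0:
        raise ValueError("agreement must lie in [0, 1]")
    if config.concentration <= 0:
        raise ValueError("concentration must be positive")
    accs = config.resolved_accuracies()
    rng = np.random.default_rng(config.seed)
    leaf_index = {l: i for i, l in enumerate(taxonomy.leaf_order)}
    try:
        true_idx = np.array([leaf_index[t] for t in truth])
    except KeyError as exc:
        raise ValueError(f"truth label {exc} is not a taxonomy leaf") from None
    n = len(true_idx)
    m = config.n_models
    conf_w = _confusion_weights(taxonomy, config.same_subclass_weight)

    shared_u = rng.random(n)
    indiv_u = rng.random((m, n))
    use_shared = rng.random((m, n)) < config.agreement
    u = np.where(use_shared, shared_u[None, :], indiv_u)
    errs = u >= accs[:, None]  # error iff the uniform falls in the top (1-acc) mass

    doc_ids = [f"doc{i:05d}" for i in range(n)]
    matrices = []
    for mi in range(m):
        modal = true_idx.copy()
        for i in np.nonzero(errs[mi])[0]:
            modal[i] = rng.choice(taxonomy.n_leaves, p=conf_w[true_idx[i]])
        rows = rng.gamma(1.0, size=(n, taxonomy.n_leaves))
        rows[np.arange(n), modal] = rng.gamma(config.concentration, size=n)
        rows /= rows.sum(axis=1, keepdims=True)
        # guarantee the modal label is the argmax without changing the row's mass
        am = rows.argmax(axis=1)
        swap = am != modal
        idx = np.nonzero(swap)[0]
        rows[idx, am[idx]], rows[idx, modal[idx]] = (
            rows[idx, modal[idx]],
            rows[idx, am[idx]].copy(),
        )
        matrices.append(
            ProbabilityMatrix(doc_ids, list(taxonomy.leaf_order), rows)
        )
    return EnsembleInput(matrices=matrices, model_names=[f"sim{i}" for i in range(m)])
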