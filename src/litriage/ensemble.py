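"""Combining per-model probability matrices into ensemble decisions.

Two strategies are provided.  The probability-sum strategy adds the
rolled-up probabilities of all member models per label and takes the
highest total; it always yields a label.  The voting strategy lets each
model vote for its most probable label at the requested level — but only
when that probability reaches the per-vote threshold t_v, otherwise the
model abstains — and triggers a decision only when the top tally is a
unique maximum reaching the vote-count threshold.  The threshold is a
static count t, or is recomputed per document from the number v of
non-abstaining voters: dynamic majority ``floor(v/2)+1`` or dynamic
unanimity ``v``.  Any other situation produces the distinguished UNKNOWN
outcome, shrinking the decided subset (the coverage).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .classify import ProbabilityMatrix
from .taxonomy import Taxonomy

__all__ = [
    "UNKNOWN",
    "ABSTAIN",
    "EnsembleInput",
    "VotingConfig",
    "EnsembleDecision",
    "EnsembleConfigError",
    "probability_sum_ensemble",
    "cast_votes",
    "voting_ensemble",
    "coverage",
]

UNKNOWN = "UNKNOWN"
ABSTAIN = "ABSTAIN"
RULES = ("threshold", "majority", "unanimity")


class EnsembleConfigError(ValueError):
    """Invalid ensemble input or voting configuration."""


@dataclass
class EnsembleInput:
    """M aligned probability matrices, one per member model."""

    matrices: list[ProbabilityMatrix]
    model_names: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.matrices) < 1:
            raise EnsembleConfigError("an ensemble needs at least one model")
        if self.model_names is None:
            self.model_names = [f"model{i}" for i in range(len(self.matrices))]
        if len(self.model_names) != len(self.matrices):
            raise EnsembleConfigError("model_names length does not match matrices")
        first = self.matrices[0]
        for m in self.matrices[1:]:
            if m.doc_ids != first.doc_ids:
                raise EnsembleConfigError("matrices do not share doc_id order")
            if m.leaf_order != first.leaf_order:
                raise EnsembleConfigError("matrices do not share leaf order")

    @property
    def n_models(self) -> int:
        return len(self.matrices)

    @property
    def doc_ids(self) -> list[str]:
        return self.matrices[0].doc_ids


@dataclass
class VotingConfig:
    """Voting-rule parameters.

    ``rule`` selects the threshold family: ``"threshold"`` uses the static
    vote count ``t``; ``"majority"`` and ``"unanimity"`` use majority /
    all-voters thresholds, computed from the M members when static or from
    the per-document non-abstaining voters when ``dynamic``.  ``t_v`` is
    the probability a model's top label must reach for the model to vote.
    """

    t: int = 3
    t_v: float = 0.0
    rule: str = "threshold"
    dynamic: bool = False

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise EnsembleConfigError(f"unknown rule {self.rule!r}")
        if not 0.0 <= self.t_v <= 1.0:
            raise EnsembleConfigError("t_v must lie in [0, 1]")
        if self.rule == "threshold" and self.t < 1:
            raise EnsembleConfigError("threshold t must be >= 1")


@dataclass
class EnsembleDecision:
    """Per-document ensemble outcome at one level, with vote bookkeeping."""

    doc_ids: list[str]
    level: str
    labels: list[str]  # label or UNKNOWN
    votes: list[list[str]]  # per document: per-model cast label or ABSTAIN
    config: VotingConfig | None = None

    def vote_counts(self, i: int) -> Counter:
        return Counter(v for v in self.votes[i] if v != ABSTAIN)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"doc_id": self.doc_ids, "label": self.labels})


def _rolled(inputs: EnsembleInput, taxonomy: Taxonomy, level: str) -> np.ndarray:
    """Stack of rolled-up matrices, shape (M, n_docs, n_level_labels)."""
    if inputs.matrices[0].leaf_order != list(taxonomy.leaf_order):
        raise EnsembleConfigError("input leaf order does not match taxonomy")
    return np.stack([taxonomy.roll_up_matrix(m.values, level) for m in inputs.matrices])


def probability_sum_ensemble(
    inputs: EnsembleInput,
    taxonomy: Taxonomy,
    level: str,
    normalize: bool = False,
) -> tuple[list[str], pd.DataFrame]:
    """Sum rolled-up probabilities across models; highest total wins.

    Returns the per-document labels and the summed scores (range
    ``[0, M]``; divided by M when ``normalize``).  Ties go to the earlier
    label in canonical order.  This strategy never abstains.
    """
    scores = _rolled(inputs, taxonomy, level).sum(axis=0)
    if normalize:
        scores = scores / inputs.n_models
    labels_at = taxonomy.labels_at(level)
    labels = [labels_at[i] for i in np.argmax(scores, axis=1)]
    frame = pd.DataFrame(scores, index=inputs.doc_ids, columns=list(labels_at))
    return labels, frame


def cast_votes(
    inputs: EnsembleInput, taxonomy: Taxonomy, level: str, t_v: float = 0.0
) -> list[list[str]]:
    """Each model's vote per document: its rolled-up argmax label, or ABSTAIN.

    A model votes iff its top label's probability reaches ``t_v``
    (inclusive); with ``t_v = 0`` every model votes.  Returned as one list
    per document, in model order.
    """
    if not 0.0 <= t_v <= 1.0:
        raise EnsembleConfigError("t_v must lie in [0, 1]")
    stack = _rolled(inputs, taxonomy, level)  # (M, n, L)
    labels_at = taxonomy.labels_at(level)
    arg = np.argmax(stack, axis=2)
    top = np.take_along_axis(stack, arg[:, :, None], axis=2)[:, :, 0]
    n_docs = stack.shape[1]
    return [
        [
            labels_at[arg[m, i]] if top[m, i] >= t_v else ABSTAIN
            for m in range(inputs.n_models)
        ]
        for i in range(n_docs)
    ]


def _effective_threshold(config: VotingConfig, n_models: int, v: int) -> int:
    if config.rule == "threshold":
        return config.t
    if config.rule == "majority":
        base = v if config.dynamic else n_models
        return base // 2 + 1
    # unanimity
    return v if config.dynamic else n_models


def voting_ensemble(
    inputs: EnsembleInput,
    taxonomy: Taxonomy,
    level: str,
    config: VotingConfig,
) -> EnsembleDecision:
    """Vote-based ensemble decision with abstention.

    Votes are cast via :func:`cast_votes` at ``config.t_v``; a document is
    decided for the top-voted label only when that tally is the unique
    maximum and reaches the effective threshold.  Ties, insufficient
    tallies, and documents where every model abstained yield UNKNOWN.
    """
    if config.rule == "threshold" and config.t > inputs.n_models:
        raise EnsembleConfigError(
            f"static threshold t={config.t} exceeds the number of models ({inputs.n_models})"
        )
    votes = cast_votes(inputs, taxonomy, level, config.t_v)
    labels: list[str] = []
    for per_doc in votes:
        tally = Counter(v for v in per_doc if v != ABSTAIN)
        v = sum(tally.values())
        if v == 0:
            labels.append(UNKNOWN)
            continue
        thr = _effective_threshold(config, inputs.n_models, v)
        best_count = max(tally.values())
        leaders = [lab for lab, c in tally.items() if c == best_count]
        if best_count >= max(thr, 1) and len(leaders) == 1:
            labels.append(leaders[0])
        else:
            labels.append(UNKNOWN)
    return EnsembleDecision(
        doc_ids=inputs.doc_ids, level=level, labels=labels, votes=votes, config=config
    )


def coverage(decisions: EnsembleDecision | Iterable[str]) -> float:
    """Fraction of documents with a decided (non-UNKNOWN) label."""
    labels = decisions.labels if isinstance(decisions, EnsembleDecision) else list(decisions)
    if not len(labels):
        raise ValueError("coverage is undefined for an empty decision set")
    return float(np.mean([l != UNKNOWN for l in labels]))
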