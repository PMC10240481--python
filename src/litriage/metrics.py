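"""Evaluation battery: classification, ranking, significance, coverage.

Per-label metrics follow the one-vs-rest contingency definitions
(precision = tp/(tp+fp), recall = tp/(tp+fn), F1 = their harmonic mean,
fp rate = fp/(fp+tn)); micro averages pool counts over labels, macro
averages take the unweighted mean of per-label metrics.  Zero
denominators yield 0 so macro averages stay defined for never-predicted
rare labels.  The ranking view treats the leaf distribution as a ranked
list of suggestions: P@k, R@k and MAP@k with exactly one relevant label
per document.  Uncertainty is quantified with percentile bootstrap CIs
(default 2000 resamples, 2.5/97.5 percentiles) and paired classifiers are
compared with McNemar's test on their discordant correctness counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score

from .classify import ProbabilityMatrix
from .ensemble import UNKNOWN, EnsembleInput, VotingConfig, coverage as _coverage, voting_ensemble
from .taxonomy import Taxonomy

__all__ = [
    "ContingencyCounts",
    "contingency",
    "precision",
    "recall",
    "f1",
    "fp_rate",
    "per_label_counts",
    "micro_macro",
    "confusion",
    "roc_auc",
    "BootstrapResult",
    "bootstrap_ci",
    "McNemarResult",
    "mcnemar",
    "RankingReport",
    "ranking_metrics",
    "pr_curve",
    "kvote_grid",
    "MetricsReport",
    "evaluate_level",
]


# ---------------------------------------------------------------------- #
# contingency counts and derived metrics


@dataclass(frozen=True)
class ContingencyCounts:
    """One-vs-rest counts for a single target label."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def contingency(y_true: Sequence, y_pred: Sequence, label) -> ContingencyCounts:
    """One-vs-rest contingency counts of ``label``."""
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    t = np.asarray(y_true) == label
    p = np.asarray(y_pred) == label
    return ContingencyCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
        tn=int(np.sum(~t & ~p)),
    )


def precision(c: ContingencyCounts) -> float:
    return c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0


def recall(c: ContingencyCounts) -> float:
    return c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0


def f1(c: ContingencyCounts) -> float:
    p, r = precision(c), recall(c)
    return 2 * p * r / (p + r) if (p + r) else 0.0


def fp_rate(c: ContingencyCounts) -> float:
    return c.fp / (c.fp + c.tn) if (c.fp + c.tn) else 0.0


def per_label_counts(
    y_true: Sequence, y_pred: Sequence, labels: Sequence
) -> dict[str, ContingencyCounts]:
    return {lab: contingency(y_true, y_pred, lab) for lab in labels}


def micro_macro(counts: Mapping[str, ContingencyCounts]) -> dict[str, float]:
    """Micro (pooled counts) and macro (unweighted mean) P/R/F1 aggregates."""
    pooled = ContingencyCounts(
        tp=sum(c.tp for c in counts.values()),
        fp=sum(c.fp for c in counts.values()),
        fn=sum(c.fn for c in counts.values()),
        tn=sum(c.tn for c in counts.values()),
    )
    per = {lab: (precision(c), recall(c), f1(c)) for lab, c in counts.items()}
    return {
        "micro_precision": precision(pooled),
        "micro_recall": recall(pooled),
        "micro_f1": f1(pooled),
        "macro_precision": float(np.mean([v[0] for v in per.values()])),
        "macro_recall": float(np.mean([v[1] for v in per.values()])),
        "macro_f1": float(np.mean([v[2] for v in per.values()])),
    }


def confusion(
    y_true: Sequence, y_pred: Sequence, taxonomy: Taxonomy, level: str
) -> pd.DataFrame:
    """Square count matrix in canonical level-label order; rows are truth."""
    labels = list(taxonomy.labels_at(level))
    m = _sk_confusion(y_true, y_pred, labels=labels)
    return pd.DataFrame(m, index=labels, columns=labels)


# ---------------------------------------------------------------------- #
# ROC / AUC


def roc_auc(
    y_true: Sequence,
    probs: ProbabilityMatrix,
    taxonomy: Taxonomy,
    level: str,
) -> tuple[float, dict[str, float]]:
    """Macro one-vs-rest AUC-ROC at ``level`` from rolled-up probabilities.

    Each level label's ROC is swept over that label's probability; labels
    absent from the truth (or covering it entirely) are skipped with a
    warning.  Returns the macro average and the per-label AUCs.
    """
    truth_at = [taxonomy.ancestor(t, level) for t in y_true]
    scores = taxonomy.roll_up_matrix(probs.values, level)
    per_label: dict[str, float] = {}
    for j, lab in enumerate(taxonomy.labels_at(level)):
        y = np.asarray(truth_at) == lab
        if y.all() or not y.any():
            warnings.warn(f"label {lab!r} absent from one truth class; skipped", stacklevel=2)
            continue
        per_label[lab] = float(roc_auc_score(y, scores[:, j]))
    if not per_label:
        raise ValueError("no label had both positive and negative truth examples")
    return float(np.mean(list(per_label.values()))), per_label


# ---------------------------------------------------------------------- #
# bootstrap


@dataclass(frozen=True)
class BootstrapResult:
    point: float
    lower: float
    upper: float
    n_boot: int
    n_redrawn: int = 0


def bootstrap_ci(
    metric: Callable[..., float],
    *data: Sequence,
    n_boot: int = 2000,
    percentiles: tuple[float, float] = (2.5, 97.5),
    seed: int | None = None,
    max_consecutive_failures: int = 1000,
) -> BootstrapResult:
    """Percentile bootstrap CI of ``metric`` over paired document arrays.

    Documents are resampled with replacement ``n_boot`` times; a resample
    on which the metric is undefined (raises, or returns a non-finite
    value — e.g. a one-class resample for AUC) is redrawn and counted.
    Bit-reproducible from ``seed``.
    """
    if not data or not len(data[0]):
        raise ValueError("bootstrap requires non-empty data")
    n = len(data[0])
    if any(len(d) != n for d in data):
        raise ValueError("all data arrays must have equal length")
    arrays = [np.asarray(d) for d in data]
    point = float(metric(*arrays))
    rng = np.random.default_rng(seed)
    values = np.empty(n_boot)
    n_redrawn = 0
    for b in range(n_boot):
        failures = 0
        while True:
            idx = rng.integers(0, n, size=n)
            try:
                v = float(metric(*(a[idx] for a in arrays)))
            except Exception:
                v = np.nan
            if np.isfinite(v):
                values[b] = v
                break
            n_redrawn += 1
            failures += 1
            if failures >= max_consecutive_failures:
                raise ValueError(
                    "metric undefined on every resample; cannot bootstrap"
                )
    lo, hi = np.percentile(values, percentiles)
    return BootstrapResult(point, float(lo), float(hi), n_boot, n_redrawn)


# ---------------------------------------------------------------------- #
# McNemar


@dataclass(frozen=True)
class McNemarResult:
    statistic: float
    p_value: float
    b: int  # documents only classifier A got right
    c: int  # documents only classifier B got right
    method: str  # "exact" or "chi2"


def mcnemar(
    correct_a: Sequence[bool],
    correct_b: Sequence[bool],
    exact_threshold: int = 25,
) -> McNemarResult:
    """Paired McNemar test on two classifiers' per-document correctness.

    With fewer than ``exact_threshold`` discordant pairs the exact
    two-sided binomial test is used (statistic = min(b, c)); otherwise the
    continuity-corrected chi-square ``(|b - c| - 1)^2 / (b + c)`` with one
    degree of freedom.  No discordant pairs gives statistic 0, p = 1.
    """
    a = np.asarray(correct_a, dtype=bool)
    bb = np.asarray(correct_b, dtype=bool)
    if a.shape != bb.shape:
        raise ValueError("correctness vectors must have equal length")
    b = int(np.sum(a & ~bb))
    c = int(np.sum(~a & bb))
    m = b + c
    if m == 0:
        return McNemarResult(0.0, 1.0, b, c, "exact")
    if m < exact_threshold:
        stat = float(min(b, c))
        p = min(1.0, 2.0 * float(stats.binom.cdf(min(b, c), m, 0.5)))
        return McNemarResult(stat, p, b, c, "exact")
    stat = (abs(b - c) - 1) ** 2 / m
    p = float(stats.chi2.sf(stat, df=1))
    return McNemarResult(float(stat), p, b, c, "chi2")


# ---------------------------------------------------------------------- #
# ranking


@dataclass
class _RankingScores:
    """Unvalidated score container for rank-only computations."""

    doc_ids: list
    leaf_order: list
    values: np.ndarray

    @property
    def n_docs(self) -> int:
        return len(self.doc_ids)


@dataclass
class RankingReport:
    """P@k / R@k / MAP@k table over the requested k values."""

    table: pd.DataFrame  # indexed by k, columns precision_at_k/recall_at_k/map_at_k
    n_docs: int

    def at(self, k: int) -> pd.Series:
        return self.table.loc[k]


def ranking_metrics(
    y_true: Sequence[str], probs: ProbabilityMatrix | pd.DataFrame, ks: Sequence[int]
) -> RankingReport:
    """Top-k ranking metrics for single-label truth.

    Leaves are ranked by descending probability (ties resolved toward the
    earlier leaf in column order).  Per document, P@k = hits-in-top-k / k,
    R@k = 1 if the true leaf ranks within k, and AP@k reduces to
    1/rank(true) when within k because exactly one label is relevant;
    report values are means over documents.  Hence P@1 = R@1 = MAP@1 and
    R@L = 1 at L = number of leaves.  Only the ranking matters, so any
    documents × leaves score frame (not necessarily row-normalized) is
    accepted in place of a probability matrix.
    """
    if isinstance(probs, pd.DataFrame):
        probs = _RankingScores(list(probs.index), list(probs.columns), probs.to_numpy(float))
    n_leaves = len(probs.leaf_order)
    ks = list(ks)
    for k in ks:
        if not 1 <= k <= n_leaves:
            raise ValueError(f"k={k} outside [1, {n_leaves}]")
    if len(y_true) != probs.n_docs:
        raise ValueError("y_true length does not match matrix")
    col = {leaf: j for j, leaf in enumerate(probs.leaf_order)}
    true_idx = np.array([col[t] for t in y_true])
    # stable argsort of -p: ties keep lower column index (earlier leaf) first
    order = np.argsort(-probs.values, axis=1, kind="stable")
    ranks = np.argmax(order == true_idx[:, None], axis=1)  # 0-based rank of truth
    rows = []
    for k in ks:
        hit = ranks < k
        rows.append(
            {
                "precision_at_k": float(np.mean(hit / k)),
                "recall_at_k": float(np.mean(hit)),
                "map_at_k": float(np.mean(np.where(hit, 1.0 / (ranks + 1), 0.0))),
            }
        )
    table = pd.DataFrame(rows, index=pd.Index(ks, name="k"))
    return RankingReport(table=table, n_docs=probs.n_docs)


# ---------------------------------------------------------------------- #
# precision/recall curve


def pr_curve(y_true: Sequence[bool], scores: Sequence[float]) -> pd.DataFrame:
    """Precision/recall points from a descending threshold sweep.

    One point per distinct score value, predicting positive at
    score >= threshold; the lowest threshold yields the recall-1
    endpoint.  Requires both classes present in the truth.
    """
    y = np.asarray(y_true, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("lengths differ")
    if y.all() or not y.any():
        raise ValueError("PR curve undefined for one-class truth")
    n_pos = int(y.sum())
    rows = []
    for thr in np.unique(s)[::-1]:
        pred = s >= thr
        tp = int(np.sum(pred & y))
        rows.append(
            {
                "threshold": float(thr),
                "recall": tp / n_pos,
                "precision": tp / int(pred.sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------- #
# level evaluation report


@dataclass
class MetricsReport:
    """Per-label and aggregate classification metrics at one level."""

    level: str
    per_label: pd.DataFrame  # precision/recall/f1/fp_rate/support per label
    aggregates: dict[str, float]
    confusion: pd.DataFrame
    n_evaluated: int
    coverage: float = 1.0

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "n_evaluated": self.n_evaluated,
            "coverage": self.coverage,
            "aggregates": self.aggregates,
            "per_label": self.per_label.to_dict(orient="index"),
            "confusion": self.confusion.to_dict(orient="index"),
        }


def evaluate_level(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    taxonomy: Taxonomy,
    level: str,
    unknown_policy: str = "exclude",
) -> MetricsReport:
    """Full per-level report from truth and predicted labels.

    ``y_true`` holds leaf labels (rolled up internally); ``y_pred`` holds
    level labels and may contain UNKNOWN.  Abstentions are excluded from
    the metrics by default (coverage reported alongside); the strict
    ``"wrong"`` policy keeps them as always-incorrect predictions.
    """
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    if unknown_policy not in ("exclude", "wrong"):
        raise ValueError(f"unknown unknown_policy {unknown_policy!r}")
    truth = [taxonomy.ancestor(t, level) for t in y_true]
    pred = list(y_pred)
    n_total = len(truth)
    if unknown_policy == "exclude":
        keep = [i for i, p in enumerate(pred) if p != UNKNOWN]
        truth = [truth[i] for i in keep]
        pred = [pred[i] for i in keep]
    cov = len([p for p in pred if p != UNKNOWN]) / n_total if n_total else 1.0
    labels = list(taxonomy.labels_at(level))
    counts = per_label_counts(truth, pred, labels)
    per_label = pd.DataFrame(
        {
            lab: {
                "precision": precision(c),
                "recall": recall(c),
                "f1": f1(c),
                "fp_rate": fp_rate(c),
                "support": c.tp + c.fn,
            }
            for lab, c in counts.items()
        }
    ).T
    conf = confusion(truth, pred, taxonomy, level) if pred else pd.DataFrame(
        0, index=labels, columns=labels
    )
    return MetricsReport(
        level=level,
        per_label=per_label,
        aggregates=micro_macro(counts),
        confusion=conf,
        n_evaluated=len(truth),
        coverage=cov,
    )


# ---------------------------------------------------------------------- #
# k-vote coverage/performance grid


def kvote_grid(
    inputs: EnsembleInput,
    y_true: Sequence[str],
    taxonomy: Taxonomy,
    level: str,
    target_label: str,
    t_values: Sequence[int] = (3, 4, 5),
    t_v_values: Sequence[float] = (0.0, 0.5, 0.9),
    rules: Sequence[tuple[str, bool]] = (
        ("majority", False),
        ("majority", True),
        ("unanimity", False),
        ("unanimity", True),
    ),
) -> pd.DataFrame:
    """Coverage/performance trade-off table for the voting ensemble.

    One row per configuration: static vote-count thresholds ``t_values``
    and the (rule, dynamic) pairs in ``rules``, each crossed with every
    per-vote threshold in ``t_v_values``.  Precision/recall/F1 target
    ``target_label`` one-vs-rest and are computed over decided documents
    only; a configuration deciding nothing reports coverage 0 and NaN
    metrics.
    """
    truth = [taxonomy.ancestor(t, level) for t in y_true]
    rows = []
    configs = [("threshold", False, t) for t in t_values]
    configs += [(rule, dynamic, None) for rule, dynamic in rules]
    for rule, dynamic, t in configs:
        for t_v in t_v_values:
            config = VotingConfig(t=t or 1, t_v=t_v, rule=rule, dynamic=dynamic)
            decision = voting_ensemble(inputs, taxonomy, level, config)
            cov = _coverage(decision)
            decided = [
                (tr, p) for tr, p in zip(truth, decision.labels) if p != UNKNOWN
            ]
            if decided:
                c = contingency([d[0] for d in decided], [d[1] for d in decided], target_label)
                p_, r_, f_ = precision(c), recall(c), f1(c)
            else:
                p_ = r_ = f_ = float("nan")
            rows.append(
                {
                    "rule": rule,
                    "dynamic": dynamic,
                    "t": t if t is not None else pd.NA,
                    "t_v": t_v,
                    "coverage": cov,
                    "n_decided": len(decided),
                    "precision": p_,
                    "recall": r_,
                    "f1": f_,
                }
            )
    return pd.DataFrame(rows)
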