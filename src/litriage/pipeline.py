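"""End-to-end k-fold cross-validation of baseline(s) plus ensemble.

For each fold: fit the baseline member(s) on the train split (members
beyond the first are diversified by bootstrap-resampling the training
documents), predict leaf probabilities on the test split, combine by
probability sum, and evaluate at all three levels.  Final metrics are
the unweighted mean over folds (the k test sets are equal-sized by
construction); a manifest records the configuration, derived seeds and
taxonomy fingerprint so a rerun is bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .classify import BaselineClassifier
from .corpus import Corpus, filter_incomplete, kfold_split
from .ensemble import EnsembleInput, probability_sum_ensemble
from .metrics import evaluate_level
from .taxonomy import LEVELS, Taxonomy

__all__ = ["CrossvalResult", "run_crossval"]

logger = logging.getLogger(__name__)


@dataclass
class CrossvalResult:
    """Per-fold and averaged metrics plus the reproducibility manifest."""

    fold_reports: list[dict]  # one {level: metrics dict} per fold
    mean_report: dict  # {level: {metric: mean over folds}}
    manifest: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "manifest": self.manifest,
                    "mean": self.mean_report,
                    "folds": self.fold_reports,
                },
                indent=2,
                sort_keys=True,
            ),
            encoding="utf-8",
        )


def run_crossval(
    corpus: Corpus,
    taxonomy: Taxonomy,
    k: int = 5,
    seed: int = 0,
    n_models: int = 1,
    c_grid: Sequence[float] = (0.001, 0.01, 0.1, 1.0, 10.0),
    stratified: bool = True,
) -> CrossvalResult:
    """Cross-validate the baseline pipeline on a labeled corpus."""
    if k < 2:
        raise ValueError("cross-validation requires k >= 2")
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    corpus, excluded = filter_incomplete(corpus)
    logger.info("corpus: %d records kept, %d excluded", len(corpus), len(excluded))
    # test sets tile the corpus; the rest splits into train/dev at 7:1,
    # matching the 70/10/20 proportions at the default k=5
    test_frac = 1.0 / k
    folds = kfold_split(
        corpus,
        k=k,
        train_frac=(1 - test_frac) * 7 / 8,
        dev_frac=(1 - test_frac) / 8,
        test_frac=test_frac,
        seed=seed,
        stratified=stratified,
    )
    rng = np.random.default_rng(seed)
    model_seeds = [
        [int(rng.integers(2**31)) for _ in range(n_models)] for _ in range(k)
    ]
    by_id = {r.doc_id: r for r in corpus}
    fold_reports: list[dict] = []
    for fold in folds:
        train = Corpus([by_id[d] for d in fold.doc_ids_with_role("train")])
        dev = Corpus([by_id[d] for d in fold.doc_ids_with_role("dev")])
        test = Corpus([by_id[d] for d in fold.doc_ids_with_role("test")])
        matrices = []
        for mi in range(n_models):
            mseed = model_seeds[fold.fold_index][mi]
            if mi == 0:
                member_train = train
            else:
                mrng = np.random.default_rng(mseed)
                idx = mrng.integers(0, len(train), size=len(train))
                members = [train.records[i] for i in idx]
                # bootstrap duplicates get fresh ids to keep the corpus valid
                members = [
                    type(r)(f"{r.doc_id}#b{j}", r.title, r.abstract, r.source, r.label)
                    for j, r in enumerate(members)
                ]
                member_train = Corpus(members)
            model = BaselineClassifier(
                taxonomy, model_name=f"baseline{mi}", c_grid=c_grid, seed=mseed
            )
            model.fit(member_train, dev)
            matrices.append(model.predict_proba(test))
        report = {}
        inputs = EnsembleInput(matrices)
        y_true = [r.label for r in test]
        for level in LEVELS:
            pred, _ = probability_sum_ensemble(inputs, taxonomy, level)
            rep = evaluate_level(y_true, pred, taxonomy, level)
            report[level] = {
                "n_evaluated": rep.n_evaluated,
                **{k_: float(v) for k_, v in rep.aggregates.items()},
            }
        logger.info(
            "fold %d: train=%d dev=%d test=%d micro_f1(class)=%.4f",
            fold.fold_index,
            len(train),
            len(dev),
            len(test),
            report["class"]["micro_f1"],
        )
        fold_reports.append(report)
    mean_report = {
        level: {
            key: float(np.mean([fr[level][key] for fr in fold_reports]))
            for key in fold_reports[0][level]
        }
        for level in LEVELS
    }
    manifest = {
        "litriage_version": __version__,
        "taxonomy_fingerprint": taxonomy.fingerprint,
        "k": k,
        "seed": seed,
        "n_models": n_models,
        "c_grid": list(c_grid),
        "stratified": stratified,
        "model_seeds": model_seeds,
        "n_documents": len(corpus),
        "n_excluded": len(excluded),
    }
    return CrossvalResult(fold_reports=fold_reports, mean_report=mean_report, manifest=manifest)
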