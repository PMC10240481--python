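"""Annotated publication corpora: reading, validation, preprocessing, splits.

A corpus is an ordered collection of publication records (id, title,
abstract, source, optional leaf label).  Records missing a title or an
abstract are excluded before training; the remaining free-text fields are
concatenated (title, abstract, source, single-space separated) to form the
classifier input.  Cross-validation uses k disjoint test sets tiling the
corpus, with the remaining documents of each fold split into train and dev
sets at 70/10/20 overall proportions.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

from .taxonomy import Taxonomy

__all__ = [
    "DocumentRecord",
    "Corpus",
    "FoldAssignment",
    "CorpusFormatError",
    "CorpusValidationError",
    "read_corpus",
    "write_corpus",
    "filter_incomplete",
    "compose_input_text",
    "kfold_split",
    "write_folds",
    "read_folds",
]

_FIELDS = ("doc_id", "title", "abstract", "source", "label")
_REQUIRED = ("doc_id", "title", "abstract", "source")
ROLES = ("train", "dev", "test")


class CorpusFormatError(ValueError):
    """The file cannot be parsed into records (missing columns, bad rows)."""


class CorpusValidationError(ValueError):
    """Parsed records violate corpus invariants (duplicate ids, bad labels)."""


@dataclass
class DocumentRecord:
    """One publication: id, free-text metadata, and an optional leaf label."""

    doc_id: str
    title: str = ""
    abstract: str = ""
    source: str = ""
    label: str | None = None


class Corpus:
    """Ordered collection of :class:`DocumentRecord` with unique ids."""

    def __init__(self, records: Iterable[DocumentRecord], taxonomy: Taxonomy | None = None):
        self.records: list[DocumentRecord] = list(records)
        seen: set[str] = set()
        for rec in self.records:
            if rec.doc_id in seen:
                raise CorpusValidationError(f"duplicate doc_id {rec.doc_id!r}")
            seen.add(rec.doc_id)
        if taxonomy is not None:
            for rec in self.records:
                if rec.label is not None and rec.label != "":
                    rec.label = taxonomy.resolve(rec.label)
                    if taxonomy[rec.label].level != "sub-subclass":
                        raise CorpusValidationError(
                            f"doc {rec.doc_id!r}: label {rec.label!r} is not a leaf"
                        )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[DocumentRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Corpus(self.records[i])
        return self.records[i]

    @property
    def doc_ids(self) -> list[str]:
        return [r.doc_id for r in self.records]

    @property
    def labels(self) -> list[str | None]:
        return [r.label for r in self.records]

    def subset(self, doc_ids: Iterable[str]) -> "Corpus":
        wanted = set(doc_ids)
        return Corpus([r for r in self.records if r.doc_id in wanted])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "doc_id": r.doc_id,
                    "title": r.title,
                    "abstract": r.abstract,
                    "source": r.source,
                    "label": "" if r.label is None else r.label,
                }
                for r in self.records
            ],
            columns=list(_FIELDS),
        )


# ---------------------------------------------------------------------- #
# file formats


def _record_from_mapping(raw: dict, where: str) -> DocumentRecord:
    missing = [k for k in _REQUIRED if k not in raw]
    if missing:
        raise CorpusFormatError(f"{where}: missing field(s) {missing}")
    label = raw.get("label")
    if label in ("", None):
        label = None
    return DocumentRecord(
        doc_id=str(raw["doc_id"]),
        title=str(raw["title"] or ""),
        abstract=str(raw["abstract"] or ""),
        source=str(raw["source"] or ""),
        label=label,
    )


def read_corpus(
    path: str | Path, format: str | None = None, taxonomy: Taxonomy | None = None
) -> Corpus:
    """Read a corpus from JSONL (one record per line) or CSV (RFC-4180).

    The format is inferred from the suffix when not given.  Unparseable
    rows are reported with their line numbers; duplicate ids and labels
    outside the taxonomy raise validation errors naming the offender.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format == "jsonl":
        records = []
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    raw = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(f"{path}:{lineno}: invalid JSON ({exc})") from None
                records.append(_record_from_mapping(raw, f"{path}:{lineno}"))
        return Corpus(records, taxonomy=taxonomy)
    if format == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [k for k in _REQUIRED if k not in df.columns]
        if missing:
            raise CorpusFormatError(f"{path}: missing column(s) {missing}")
        if "label" not in df.columns:
            df["label"] = ""
        records = [
            _record_from_mapping(row, f"{path}: row {i + 2}")
            for i, row in enumerate(df[list(_FIELDS)].to_dict("records"))
        ]
        return Corpus(records, taxonomy=taxonomy)
    raise CorpusFormatError(f"unknown corpus format {format!r}")


def write_corpus(corpus: Corpus, path: str | Path, format: str | None = None) -> None:
    """Write a corpus as JSONL or CSV; round-trips through :func:`read_corpus`."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for r in corpus:
                fh.write(
                    json.dumps(
                        {
                            "doc_id": r.doc_id,
                            "title": r.title,
                            "abstract": r.abstract,
                            "source": r.source,
                            "label": "" if r.label is None else r.label,
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )
    elif format == "csv":
        corpus.to_frame().to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL)
    else:
        raise CorpusFormatError(f"unknown corpus format {format!r}")


# ---------------------------------------------------------------------- #
# preprocessing


def filter_incomplete(corpus: Corpus) -> tuple[Corpus, list[dict]]:
    """Drop records without a title or abstract.

    Returns the retained corpus and an exclusion report listing each
    excluded ``doc_id`` with its reason.  A missing source is *not* a
    reason for exclusion; the composed input text simply omits it.
    """
    kept, report = [], []
    for rec in corpus:
        if not rec.title.strip():
            report.append({"doc_id": rec.doc_id, "reason": "missing title"})
        elif not rec.abstract.strip():
            report.append({"doc_id": rec.doc_id, "reason": "missing abstract"})
        else:
            kept.append(rec)
    return Corpus(kept), report


def compose_input_text(record: DocumentRecord) -> str:
    """Concatenate title, abstract, source (in that order) with single spaces.

    Fields are stripped of surrounding whitespace; an absent source
    contributes nothing.  Deterministic and idempotent.
    """
    parts = [p.strip() for p in (record.title, record.abstract, record.source)]
    return " ".join(p for p in parts if p)


# ---------------------------------------------------------------------- #
# cross-validation splits


@dataclass
class FoldAssignment:
    """Role (train/dev/test) of every document in one cross-validation fold."""

    fold_index: int
    roles: dict[str, str] = field(default_factory=dict)

    def doc_ids_with_role(self, role: str) -> list[str]:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        return [d for d, r in self.roles.items() if r == role]


def kfold_split(
    corpus: Corpus,
    k: int = 5,
    train_frac: float = 0.7,
    dev_frac: float = 0.1,
    test_frac: float = 0.2,
    seed: int = 0,
    stratified: bool = True,
) -> list[FoldAssignment]:
    """Split a labeled corpus into k folds with train/dev/test roles.

    The k test sets are disjoint and tile the corpus (``k * test_frac``
    must equal 1); within each fold the non-test documents are split into
    train and dev at ``train_frac : dev_frac``.  Splits are stratified by
    leaf label by default; a leaf rarer than k documents triggers a
    warning and label-blind assignment for the affected split.
    """
    if abs(train_frac + dev_frac + test_frac - 1.0) > 1e-9:
        raise ValueError("train_frac + dev_frac + test_frac must equal 1")
    if abs(k * test_frac - 1.0) > 1e-9:
        raise ValueError("k * test_frac must equal 1 so test sets tile the corpus")
    if k < 2:
        raise ValueError("k-fold cross-validation requires k >= 2")
    doc_ids = np.array(corpus.doc_ids)
    labels = np.array(["" if l is None else l for l in corpus.labels])
    if stratified and (labels == "").any():
        raise CorpusValidationError("stratified split requires a fully labeled corpus")

    use_strat = stratified
    if stratified:
        counts = pd.Series(labels).value_counts()
        rare = counts[counts < k]
        if len(rare):
            warnings.warn(
                f"leaves with fewer than k={k} documents "
                f"({', '.join(map(repr, rare.index))}); stratification relaxed",
                stacklevel=2,
            )
            use_strat = False

    if use_strat:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(doc_ids, labels)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(doc_ids)

    dev_share = dev_frac / (train_frac + dev_frac)
    folds = []
    for fold_index, (rest_idx, test_idx) in enumerate(split_iter):
        n_dev = max(1, round(len(rest_idx) * dev_share))
        strat = labels[rest_idx] if use_strat else None
        try:
            train_idx, dev_idx = train_test_split(
                rest_idx,
                test_size=n_dev,
                random_state=seed + fold_index,
                stratify=strat,
            )
        except ValueError:
            warnings.warn(
                f"fold {fold_index}: inner train/dev stratification infeasible; "
                "falling back to label-blind split",
                stacklevel=2,
            )
            train_idx, dev_idx = train_test_split(
                rest_idx, test_size=n_dev, random_state=seed + fold_index
            )
        roles: dict[str, str] = {}
        for idx, role in ((train_idx, "train"), (dev_idx, "dev"), (test_idx, "test")):
            for d in doc_ids[idx]:
                roles[d] = role
        # preserve corpus order for readability
        roles = {d: roles[d] for d in doc_ids}
        folds.append(FoldAssignment(fold_index=fold_index, roles=roles))
    return folds


def write_folds(folds: Sequence[FoldAssignment], path: str | Path) -> None:
    """Write fold assignments as delimited ``doc_id,fold,role`` rows."""
    rows = [
        {"doc_id": d, "fold": f.fold_index, "role": r}
        for f in folds
        for d, r in f.roles.items()
    ]
    pd.DataFrame(rows, columns=["doc_id", "fold", "role"]).to_csv(path, index=False)


def read_folds(path: str | Path) -> list[FoldAssignment]:
    df = pd.read_csv(path, dtype={"doc_id": str, "fold": int, "role": str})
    folds = []
    for fold_index, grp in df.groupby("fold", sort=True):
        bad = set(grp["role"]) - set(ROLES)
        if bad:
            raise CorpusFormatError(f"{path}: unknown role(s) {sorted(bad)}")
        folds.append(
            FoldAssignment(
                fold_index=int(fold_index),
                roles=dict(zip(grp["doc_id"], grp["role"])),
            )
        )
    return folds
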