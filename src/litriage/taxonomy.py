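"""Nested study-design label space and probability/count roll-ups.

A taxonomy has three fixed levels — class, subclass, sub-subclass — with
every sub-subclass ("leaf") nested in exactly one subclass and every
subclass in exactly one class.  Classifiers emit probability distributions
over the leaves; probabilities at a coarser level are obtained by summing
the probabilities of all descendant leaves, so a document's class
probability is the total probability mass of the sub-subclasses mapped to
that class.

The default taxonomy shipped with the package is the COVID-19 Open Access
Project (COAP) living-evidence scheme: 22 sub-subclasses nested into the
EPI / BASIC / OTHER subclasses, which nest into the ORIGINAL /
NON-ORIGINAL classes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LEVELS",
    "CLASS",
    "SUBCLASS",
    "SUBSUBCLASS",
    "LabelNode",
    "Taxonomy",
    "TaxonomyError",
    "load_taxonomy",
    "default_taxonomy",
    "coap_leaf_counts",
]

LEVELS = ("class", "subclass", "sub-subclass")
CLASS, SUBCLASS, SUBSUBCLASS = LEVELS

#: parent level expected for a node of each level (None = no parent).
_PARENT_LEVEL = {CLASS: None, SUBCLASS: CLASS, SUBSUBCLASS: SUBCLASS}


class TaxonomyError(ValueError):
    """A taxonomy specification or roll-up input violates its contract."""


@dataclass(frozen=True)
class LabelNode:
    """One label in the nested scheme.

    Parameters
    ----------
    id : str
        Short stable key, unique within a taxonomy.
    name : str
        Display string.
    level : str
        One of ``"class"``, ``"subclass"``, ``"sub-subclass"``.
    parent : str or None
        Id of the node one level up; ``None`` for class-level nodes.
    """

    id: str
    name: str
    level: str
    parent: str | None = None


class Taxonomy:
    """Validated three-level label hierarchy with roll-up operations.

    Nodes are kept in specification order; ``leaf_order`` (the order of the
    sub-subclass ids) is the column order for every probability matrix in
    the package, and label order at coarser levels is first-appearance
    order.  All silent-corruption risks therefore reduce to one explicit
    ordering.
    """

    def __init__(self, nodes: Iterable[LabelNode], aliases: Mapping[str, str] | None = None):
        self.nodes: tuple[LabelNode, ...] = tuple(nodes)
        self.aliases: dict[str, str] = dict(aliases or {})
        self._by_id: dict[str, LabelNode] = {}
        self._validate()
        self.leaf_order: tuple[str, ...] = tuple(
            n.id for n in self.nodes if n.level == SUBSUBCLASS
        )
        self._labels_at = {
            level: tuple(n.id for n in self.nodes if n.level == level) for level in LEVELS
        }
        self._membership_cache: dict[str, np.ndarray] = {}

    # ------------------------------------------------------------------ #
    # validation and lookups

    def _validate(self) -> None:
        for node in self.nodes:
            if node.level not in LEVELS:
                raise TaxonomyError(f"node {node.id!r}: unknown level {node.level!r}")
            if node.id in self._by_id:
                raise TaxonomyError(f"duplicate node id {node.id!r}")
            self._by_id[node.id] = node
        for node in self.nodes:
            want = _PARENT_LEVEL[node.level]
            if want is None:
                if node.parent is not None:
                    raise TaxonomyError(
                        f"class-level node {node.id!r} must not have a parent"
                    )
                continue
            if node.parent is None:
                raise TaxonomyError(f"orphan node {node.id!r}: no parent given")
            parent = self._by_id.get(node.parent)
            if parent is None:
                raise TaxonomyError(
                    f"orphan node {node.id!r}: parent {node.parent!r} not in taxonomy"
                )
            if parent.level != want:
                raise TaxonomyError(
                    f"node {node.id!r} at level {node.level!r} has parent "
                    f"{node.parent!r} at level {parent.level!r}; expected {want!r}"
                )

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._by_id

    def __getitem__(self, node_id: str) -> LabelNode:
        try:
            return self._by_id[node_id]
        except KeyError:
            raise TaxonomyError(f"unknown label id {node_id!r}") from None

    def resolve(self, node_id: str) -> str:
        """Resolve an id or a recorded alias to the canonical id."""
        if node_id in self._by_id:
            return node_id
        if node_id in self.aliases:
            return self.aliases[node_id]
        raise TaxonomyError(f"unknown label id {node_id!r}")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_order)

    def labels_at(self, level: str) -> tuple[str, ...]:
        """Label ids at ``level`` in canonical order."""
        if level not in LEVELS:
            raise TaxonomyError(f"unknown level {level!r}")
        return self._labels_at[level]

    def ancestor(self, leaf_id: str, level: str) -> str:
        """Unique ancestor of ``leaf_id`` at ``level`` (the leaf itself at leaf level)."""
        if level not in LEVELS:
            raise TaxonomyError(f"unknown level {level!r}")
        node = self[self.resolve(leaf_id)]
        if node.level != SUBSUBCLASS:
            raise TaxonomyError(f"{leaf_id!r} is not a sub-subclass")
        while node.level != level:
            node = self[node.parent]
        return node.id

    def leaves_under(self, label_id: str) -> tuple[str, ...]:
        """All sub-subclass ids descending from ``label_id`` (itself, if a leaf)."""
        label_id = self.resolve(label_id)
        level = self[label_id].level
        return tuple(
            leaf for leaf in self.leaf_order if self.ancestor(leaf, level) == label_id
        )

    # ------------------------------------------------------------------ #
    # roll-ups

    def membership(self, level: str) -> np.ndarray:
        """0/1 matrix of shape (labels at level, n_leaves); row i marks leaf descendants."""
        if level not in self._membership_cache:
            labels = self.labels_at(level)
            m = np.zeros((len(labels), self.n_leaves))
            index = {lab: i for i, lab in enumerate(labels)}
            for j, leaf in enumerate(self.leaf_order):
                m[index[self.ancestor(leaf, level)], j] = 1.0
            self._membership_cache[level] = m
        return self._membership_cache[level]

    def roll_up_distribution(
        self, leaf_probs: Sequence[float], level: str, atol: float = 1e-9
    ) -> pd.Series:
        """Sum leaf probabilities over each ``level`` label's descendant leaves.

        ``leaf_probs`` must be a nonnegative vector over ``leaf_order``
        summing to 1 within ``atol``; the result is a distribution over the
        labels at ``level``.
        """
        p = np.asarray(leaf_probs, dtype=float)
        if p.shape != (self.n_leaves,):
            raise TaxonomyError(
                f"expected a vector of length {self.n_leaves}, got shape {p.shape}"
            )
        if np.any(p < 0):
            raise TaxonomyError("leaf probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > atol:
            raise TaxonomyError(f"leaf probabilities sum to {p.sum()!r}, not 1")
        return pd.Series(self.membership(level) @ p, index=list(self.labels_at(level)))

    def roll_up_counts(self, leaf_counts: Sequence[int], level: str) -> pd.Series:
        """Sum integer leaf counts over each ``level`` label; grand total preserved."""
        c = np.asarray(leaf_counts)
        if c.shape != (self.n_leaves,):
            raise TaxonomyError(
                f"expected a vector of length {self.n_leaves}, got shape {c.shape}"
            )
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise TaxonomyError("leaf counts must be nonnegative integers")
        out = (self.membership(level) @ c).astype(int)
        return pd.Series(out, index=list(self.labels_at(level)))

    def roll_up_matrix(self, values: np.ndarray, level: str) -> np.ndarray:
        """Roll an (n_docs, n_leaves) probability array up to ``level`` columns."""
        values = np.asarray(values, dtype=float)
        return values @ self.membership(level).T

    # ------------------------------------------------------------------ #
    # serialization

    def to_spec(self) -> dict:
        spec: dict = {
            "nodes": [
                {"id": n.id, "name": n.name, "level": n.level, "parent": n.parent}
                for n in self.nodes
            ]
        }
        if self.aliases:
            spec["aliases"] = dict(self.aliases)
        return spec

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            yaml.safe_dump(self.to_spec(), sort_keys=False)
            if path.suffix in {".yml", ".yaml"}
            else json.dumps(self.to_spec(), indent=2)
        )
        path.write_text(text, encoding="utf-8")

    @property
    def fingerprint(self) -> str:
        """Stable hash of the node structure; stamped on artifacts to detect mismatch."""
        canon = json.dumps(self.to_spec()["nodes"], sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_taxonomy(spec: Mapping | Sequence | str | Path) -> Taxonomy:
    """Build a :class:`Taxonomy` from a declarative spec.

    ``spec`` may be a path to a JSON/YAML file, a mapping with a ``nodes``
    list (and optional ``aliases``), or a bare list of node mappings.  Leaf
    order is the order in which sub-subclass nodes appear.
    """
    if isinstance(spec, (str, Path)):
        text = Path(spec).read_text(encoding="utf-8")
        spec = yaml.safe_load(text)  # YAML is a JSON superset
    if isinstance(spec, Mapping):
        nodes_raw = spec.get("nodes")
        aliases = spec.get("aliases")
        if nodes_raw is None:
            raise TaxonomyError("taxonomy spec has no 'nodes' list")
    else:
        nodes_raw, aliases = spec, None
    nodes = []
    for raw in nodes_raw:
        try:
            nodes.append(
                LabelNode(
                    id=raw["id"],
                    name=raw.get("name", raw["id"]),
                    level=raw["level"],
                    parent=raw.get("parent"),
                )
            )
        except KeyError as exc:
            raise TaxonomyError(f"node entry {raw!r} missing key {exc}") from None
    return Taxonomy(nodes, aliases=aliases)


def default_taxonomy() -> Taxonomy:
    """The packaged COAP scheme: 22 leaves, 3 subclasses, 2 classes."""
    with resources.files("litriage.data").joinpath("coap_taxonomy.json").open(
        encoding="utf-8"
    ) as fh:
        return load_taxonomy(json.load(fh))


def coap_leaf_counts() -> pd.Series:
    """Published per-leaf document counts of the COAP snapshot (6365 records).

    Used as the default leaf frequency profile of the synthetic-corpus
    generator and as a worked example for the count roll-up.
    """
    with resources.files("litriage.data").joinpath("coap_counts.json").open(
        encoding="utf-8"
    ) as fh:
        counts = json.load(fh)
    tax = default_taxonomy()
    return pd.Series([counts[leaf] for leaf in tax.leaf_order], index=list(tax.leaf_order))
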