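"""Shared fixtures: the default taxonomy and small synthetic corpora.

Heavy objects (generated corpora, fitted baselines) are session-scoped so
the suite pays for them once.
"""

import warnings

import pytest

from litriage import (
    CorpusGeneratorConfig,
    default_taxonomy,
    fit_baseline,
    generate_corpus,
    kfold_split,
)


@pytest.fixture(scope="session")
def tax():
    return default_taxonomy()


@pytest.fixture(scope="session")
def signal_corpus(tax):
    """Nearly separable synthetic corpus: strong class-conditional vocabulary."""
    return generate_corpus(
        CorpusGeneratorConfig(taxonomy=tax, n_docs=1200, signal_strength=0.95, seed=11)
    )


@pytest.fixture(scope="session")
def signal_split(signal_corpus):
    """(train, dev, test) sub-corpora from fold 0 of a stratified 5-fold split."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rare leaves relax stratification
        folds = kfold_split(signal_corpus, k=5, seed=11)
    f = folds[0]
    return (
        signal_corpus.subset(f.doc_ids_with_role("train")),
        signal_corpus.subset(f.doc_ids_with_role("dev")),
        signal_corpus.subset(f.doc_ids_with_role("test")),
    )


@pytest.fixture(scope="session")
def fitted_baseline(tax, signal_split):
    train, dev, _ = signal_split
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_baseline(train, dev, tax, seed=11)
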