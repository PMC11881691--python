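"""Shared fixtures: synthetic corpus, trained registry, tiny FASTA files.

Heavy objects (corpus, registry) are session-scoped so the suite trains
each classifier head once.
"""

from __future__ import annotations

import numpy as np
import pytest

import deepes
from deepes.embedding import embed, mock_spec
from deepes.rclass_classifier import Hyperparameters, LabeledExample

# optimisation effort comparable to the reference setting at corpus scale
# (see docs/methods.md); other hyperparameters at their defaults
E2E_HP = Hyperparameters(epochs=300)


@pytest.fixture(scope="session")
def synthetic_spec() -> deepes.SyntheticSpec:
    return deepes.SyntheticSpec()


@pytest.fixture(scope="session")
def corpus(synthetic_spec):
    return deepes.generate_corpus(synthetic_spec)


@pytest.fixture(scope="session")
def embedder_spec():
    return mock_spec()


@pytest.fixture(scope="session")
def labeled_corpus(corpus, embedder_spec) -> list[LabeledExample]:
    return [
        LabeledExample.make(
            e.gene_id, embed(e.sequence, embedder_spec), e.rclass_ids
        )
        for e in corpus.examples
    ]


@pytest.fixture(scope="session")
def pathway(corpus):
    return deepes.pathway_for_corpus(corpus)


@pytest.fixture(scope="session")
def registry(corpus, synthetic_spec, embedder_spec):
    return deepes.train_registry(
        corpus.examples,
        synthetic_spec.rclass_ids,
        embedder_spec=embedder_spec,
        hp=E2E_HP,
    )


@pytest.fixture()
def three_gene_fasta(tmp_path):
    path = tmp_path / "genes.faa"
    path.write_text(
        ">geneA descr\nMKTAYIAKQR\n"
        ">geneB\nmvlspadktnv*\n"
        ">geneC\nGSAQVKGHGKK\n"
    )
    return path


def separable_clusters(n: int = 200, D: int = 8, seed: int = 0):
    """Two well-separated Gaussian embedding clusters, 10% positives."""
    rng = np.random.default_rng(seed)
    n_pos = n // 10
    pos = rng.normal(loc=3.0, scale=0.5, size=(n_pos, D))
    neg = rng.normal(loc=-3.0, scale=0.5, size=(n - n_pos, D))
    X = np.vstack([pos, neg])
    y = np.concatenate([np.ones(n_pos), np.zeros(n - n_pos)])
    examples = [
        LabeledExample.make(
            f"g{i:04d}", X[i], {"RC_SEP"} if y[i] else set()
        )
        for i in range(n)
    ]
    return examples, X, y
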