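"""Shared fixtures: corpora, fragment records, and trained generators.

The expensive artifacts (a fully trained generator and a 10-seed
optimization run) are session-scoped and shared across tests so the
suite trains each model exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest

from fragopt import (
    FixtureSpec,
    TrainConfig,
    generate_fixture_corpus,
    load_bundled_corpus,
    optimize,
    parse_smiles,
    qed_score,
    select_seed_molecules,
    serialize_fragment,
    steps_from_corpus,
    train,
)
from fragopt.fragmenter import build_corpus
from fragopt.scoring import get_score_function


@pytest.fixture(scope="session")
def bundled_corpus() -> list[str]:
    return load_bundled_corpus()


@pytest.fixture(scope="session")
def bundled_corpus_path(tmp_path_factory, bundled_corpus):
    path = tmp_path_factory.mktemp("corpus") / "bundled.smi"
    path.write_text("\n".join(bundled_corpus) + "\n")
    return path


@pytest.fixture(scope="session")
def corpus_records(bundled_corpus_path):
    return build_corpus(bundled_corpus_path)


@pytest.fixture(scope="session")
def random_molecules() -> list[str]:
    """200 procedurally generated valid molecules for property tests."""
    return generate_fixture_corpus(FixtureSpec(n_molecules=200, seed=42))


@pytest.fixture(scope="session")
def tiny_fragment_records(corpus_records):
    """Ten small, frequent, distinct corpus fragments."""
    small = sorted((r for r in corpus_records if 2 <= r.graph.n_atoms <= 8),
                   key=lambda r: (-r.source_count, r.canonical_key))
    return small[:10]


@pytest.fixture(scope="session")
def quick_model(bundled_corpus, tmp_path_factory):
    """A lightly trained generator for search-mechanics tests."""
    path = tmp_path_factory.mktemp("quick") / "slice.smi"
    path.write_text("\n".join(bundled_corpus[:120]) + "\n")
    records = build_corpus(path)
    steps = [s for frag in steps_from_corpus(records) for s in frag]
    result = train(steps, TrainConfig(learning_rate=1e-3, batch_size=64,
                                      epochs=4, eval_epoch=4, seed=11))
    return result.model


@pytest.fixture(scope="session")
def trained_model(corpus_records):
    """Generator trained 20 epochs on the full bundled fragment corpus."""
    steps = [s for frag in steps_from_corpus(corpus_records) for s in frag]
    result = train(steps, TrainConfig(epochs=20, eval_epoch=20, seed=7))
    return result.eval_model or result.model


@pytest.fixture(scope="session")
def qed_seeds(bundled_corpus):
    """Ten starting molecules with QED in [0.6, 0.7]."""
    return select_seed_molecules(bundled_corpus, qed_score, 0.6, 0.7,
                                 n=10, rng=3)


@pytest.fixture(scope="session")
def full_optimization(trained_model, qed_seeds):
    """One 10-seed QED optimization run (20 fragment x 100 atom steps).

    Returns a list of (seed_smiles, seed_qed, ranked results) triples;
    shared by the validity and improvement acceptance tests.
    """
    qed = get_score_function("qed")
    rng = np.random.default_rng(2024)
    runs = []
    for seed_smiles in qed_seeds:
        seed = parse_smiles(seed_smiles)
        results = optimize(seed, qed, trained_model,
                           fragment_steps=20, atom_steps=100, rng=rng)
        runs.append((seed.canonical(), qed(seed), results))
    return runs
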