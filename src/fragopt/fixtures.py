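"""Offline test data: a bundled drug-like SMILES list and a procedural
generator of simple valid molecules.

The generator assembles molecules from ring systems and single atoms by
valence-checked graph edits, so everything it emits parses and satisfies
valence by construction.  It stands in for a large public screening
corpus at desk scale: molecules are drug-like in element composition and
size, mix ring-bearing and acyclic structures (so the fragmenter
produces multiple fragments for a sizable share of them), but carry no
real bioactivity.

The bundled list (``data/druglike_synthetic_500.smi``) holds 500 unique
molecules: a core of well-known public drug structures plus seeded
generator output, all RDKit-validated.  The "synthetic" in the filename
is honest: the list is a constructed stand-in for a screening corpus,
not a curated excerpt of one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .chem_graph import (
    AttachmentSite,
    DEFAULT_VOCAB,
    AtomVocab,
    MolGraph,
    ValenceError,
    attach_fragment,
    free_valence,
    parse_smiles,
)

__all__ = ["FixtureSpec", "generate_fixture_corpus", "select_seed_molecules",
           "load_bundled_corpus", "InsufficientCandidatesError"]


class InsufficientCandidatesError(ValueError):
    """Fewer molecules satisfy the requested score band than asked for."""


_RING_SMILES = (
    "c1ccccc1",      # benzene
    "c1ccncc1",      # pyridine
    "c1cc[nH]c1",    # pyrrole (stored kekulized, N-H implicit)
    "c1ccsc1",       # thiophene
    "c1ccoc1",       # furan
    "C1CCCCC1",      # cyclohexane
    "C1CCNCC1",      # piperidine
    "C1CCOCC1",      # tetrahydropyran
    "C1CCCC1",       # cyclopentane
)

_DEFAULT_WEIGHTS = {
    "C": 0.66, "N": 0.13, "O": 0.13, "F": 0.03, "P": 0.0,
    "S": 0.02, "Cl": 0.02, "Br": 0.01, "I": 0.0,
}


@dataclass
class FixtureSpec:
    """Study conditions for the procedural corpus."""

    n_molecules: int = 500
    max_atoms: int = 25
    min_atoms: int = 8
    ring_probability: float = 0.6   # chance a molecule starts from a ring
    grow_ring_probability: float = 0.12  # chance a growth step adds a ring
    element_weights: dict = field(default_factory=lambda: dict(_DEFAULT_WEIGHTS))
    seed: int = 0


def _weights_array(spec: FixtureSpec, vocab: AtomVocab) -> np.ndarray:
    w = np.array([spec.element_weights.get(e, 0.0) for e in vocab.elements])
    if w.sum() <= 0:
        raise ValueError("element_weights assign no mass to the vocabulary")
    return w / w.sum()


def _grow_molecule(spec: FixtureSpec, vocab: AtomVocab, rings: list[MolGraph],
                   rng: np.random.Generator) -> MolGraph:
    w = _weights_array(spec, vocab)
    if spec.ring_probability > 0 and rng.random() < spec.ring_probability:
        g = rings[rng.integers(len(rings))].copy()
    else:
        g = MolGraph(vocab=vocab)
        g.add_atom(int(rng.choice(len(vocab.elements), p=w)))
    target = int(rng.integers(spec.min_atoms, spec.max_atoms + 1))
    for _ in range(4 * spec.max_atoms):  # growth attempts, not atom count
        if g.n_atoms >= target:
            break
        sites = [i for i in range(g.n_atoms) if free_valence(g, i) >= 1]
        if not sites:
            break
        site = int(rng.choice(sites))
        add_ring = (rng.random() < spec.grow_ring_probability
                    and g.n_atoms + 6 <= spec.max_atoms)
        if add_ring:
            ring = rings[rng.integers(len(rings))]
            ring_sites = [i for i in range(ring.n_atoms)
                          if free_valence(ring, i) >= 1]
            if not ring_sites:
                continue
            try:
                g = attach_fragment(g, ring, AttachmentSite(
                    site, int(rng.choice(ring_sites))))
            except ValenceError:
                continue
        else:
            elem = int(rng.choice(len(vocab.elements), p=w))
            fv_site = free_valence(g, site)
            max_order = min(fv_site, vocab.max_valence[elem], 3)
            # mostly single bonds; occasional double (carbonyl-like)
            order = 1
            if max_order >= 2 and rng.random() < 0.15:
                order = 2
            new = g.add_atom(elem)
            g.add_bond(site, new, order)
    return g


def generate_fixture_corpus(spec: FixtureSpec,
                            vocab: AtomVocab = DEFAULT_VOCAB) -> list[str]:
    """Deterministically generate ``spec.n_molecules`` unique valid SMILES."""
    rng = np.random.default_rng(spec.seed)
    rings = [parse_smiles(s, vocab) for s in _RING_SMILES]
    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(out) < spec.n_molecules:
        attempts += 1
        if attempts > 100 * spec.n_molecules:
            raise RuntimeError("fixture generation failed to converge")
        g = _grow_molecule(spec, vocab, rings, rng)
        if g.n_atoms < spec.min_atoms:
            continue
        smiles = g.canonical()
        # round-trip guard: everything emitted must re-parse cleanly
        if smiles in seen:
            continue
        try:
            parse_smiles(smiles, vocab)
        except Exception:
            continue
        seen.add(smiles)
        out.append(smiles)
    return out


def select_seed_molecules(corpus: list[str], score_fn, lo: float, hi: float,
                          n: int, rng: np.random.Generator | int | None = None,
                          ) -> list[str]:
    """Randomly pick ``n`` corpus molecules whose score falls in [lo, hi]."""
    if not lo < hi:
        raise ValueError(f"need lo < hi, got [{lo}, {hi}]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    band = [s for s in corpus if lo <= score_fn(s) <= hi]
    if len(band) < n:
        raise InsufficientCandidatesError(
            f"only {len(band)} molecules score within [{lo}, {hi}], need {n}")
    picks = rng.choice(len(band), size=n, replace=False)
    return [band[i] for i in picks]


def load_bundled_corpus() -> list[str]:
    """The bundled 500-molecule drug-like SMILES fixture."""
    text = (resources.files("fragopt") / "data" /
            "druglike_synthetic_500.smi").read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]
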