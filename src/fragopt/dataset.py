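"""Teacher-forced serialization of fragments into supervised steps.

A fragment with *n* atoms becomes *n* + 1 training steps.  Atoms are
visited in BFS order from canonical atom 0; step *t* presents the induced
subgraph on the first *t* atoms as the model input, the element of atom
*t* as the atom label, and, for each of the *t* existing atoms in BFS
order, the order of the bond it shares with the new atom (or "none").
The final step carries the stop label and no bond labels.  Replaying the
steps reconstructs the fragment exactly, which is the correctness
contract tested for every corpus fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem_graph import (
    AtomVocab,
    BondVocab,
    DEFAULT_BONDS,
    DEFAULT_VOCAB,
    MolGraph,
    bfs_order,
)
from .fragmenter import FragmentRecord

__all__ = ["GenerationStep", "serialize_fragment", "replay_steps",
           "steps_from_corpus", "split_train_test", "FragmentTooLargeError"]


class FragmentTooLargeError(ValueError):
    pass


@dataclass
class GenerationStep:
    """One supervised (state -> next atom, next bonds) example.

    ``bond_labels[u]`` is the bond-vocab label between the new atom and the
    state's atom at BFS position ``u`` (``none_label`` where no bond).
    """

    state: MolGraph
    atom_label: int
    bond_labels: list[int] = field(default_factory=list)


def serialize_fragment(
    frag: MolGraph,
    max_atoms: int = 50,
    bond_vocab: BondVocab = DEFAULT_BONDS,
    root: int = 0,
) -> list[GenerationStep]:
    """Serialize a connected fragment into its BFS generation steps."""
    if frag.n_atoms > max_atoms:
        raise FragmentTooLargeError(
            f"fragment has {frag.n_atoms} atoms (max {max_atoms})"
        )
    order = bfs_order(frag, root)
    pos = {atom: t for t, atom in enumerate(order)}
    order_lookup = {1: 0, 2: 1, 3: 2}
    steps = []
    state = MolGraph(vocab=frag.vocab)
    for t, atom in enumerate(order):
        bond_labels = []
        for u in range(t):
            key = (min(order[u], atom), max(order[u], atom))
            o = frag.bonds.get(key)
            bond_labels.append(
                bond_vocab.none_label if o is None else order_lookup[o]
            )
        steps.append(GenerationStep(state.copy(), frag.atoms[atom], bond_labels))
        state.add_atom(frag.atoms[atom])
        for u, lab in enumerate(bond_labels):
            if lab != bond_vocab.none_label:
                state.add_bond(u, t, bond_vocab.orders[lab])
    steps.append(GenerationStep(state, frag.vocab.stop_label, []))
    return steps


def replay_steps(
    steps: list[GenerationStep],
    vocab: AtomVocab = DEFAULT_VOCAB,
    bond_vocab: BondVocab = DEFAULT_BONDS,
) -> MolGraph:
    """Apply a step sequence from the empty graph; inverse of serialization."""
    g = MolGraph(vocab=vocab)
    for step in steps:
        if step.atom_label == vocab.stop_label:
            break
        t = g.add_atom(step.atom_label)
        for u, lab in enumerate(step.bond_labels):
            if lab != bond_vocab.none_label:
                g.add_bond(u, t, bond_vocab.orders[lab])
    return g


def steps_from_corpus(
    records: list[FragmentRecord],
    max_atoms: int = 50,
) -> list[list[GenerationStep]]:
    """Serialize every corpus fragment (one canonical order each)."""
    return [serialize_fragment(r.graph, max_atoms) for r in records]


def split_train_test(records, ratio: float = 0.8, seed: int = 0):
    """Split fragments (not steps) into disjoint train/test reproducibly."""
    if not 0 < ratio < 1:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(records))
    n_train = int(round(len(records) * ratio))
    train = [records[i] for i in idx[:n_train]]
    test = [records[i] for i in idx[n_train:]]
    return train, test
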