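"""Inner atom-wise Monte Carlo tree search: grow one fragment.

A path through the tree is a fragment — each node adds one atom (with
its bonds) to the partial fragment of its parent.  Expansion proposes
the top-k (atom, bonds) steps from the generator, valence-masked;
rollout completes the partial fragment by sampling from the same
generator until it predicts the stop label or no bond (the terminal
conditions), with a hard cap on fragment size.  A completed fragment is
attached to the parent molecule by a single bond — fragment side: its
first generated atom; parent side: the site chosen by the outer search —
and the evaluation function applied to the attached molecule is the
reward (squashed into [−1, 1] for backpropagation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chem_graph import (
    AttachmentSite,
    MolGraph,
    ValenceError,
    attach_fragment,
    free_valence,
)
from .fragment_mcts import RewardTransform, ucb1
from .gcn_model import GeneratorModel, Proposal, apply_proposal

__all__ = ["AtomSearchNode", "ScoredCandidate", "run_atom_search", "is_terminal"]


@dataclass
class AtomSearchNode:
    partial: MolGraph
    value_sum: float = 0.0
    visits: int = 0
    parent: "AtomSearchNode | None" = None
    children: list["AtomSearchNode"] = field(default_factory=list)
    terminal: bool = False
    prior: float = 0.0

    @property
    def mean(self) -> float:
        return self.value_sum / self.visits if self.visits else 0.0


@dataclass
class ScoredCandidate:
    """A completed fragment attached to the parent molecule, with its score."""

    mol: MolGraph
    smiles: str
    raw: float
    fragment_smiles: str
    fragment_atoms: int


def is_terminal(proposal: Proposal | None, model: GeneratorModel,
                state_nonempty: bool) -> bool:
    """Terminal iff the generator stopped: empty-atom label or no bond."""
    if proposal is None:
        return True
    return proposal.is_stop(model.vocab, model.bonds, state_nonempty)


def _rollout(partial: MolGraph, model: GeneratorModel, rng,
             max_atoms: int, temperature: float) -> MolGraph:
    g = partial
    while g.n_atoms < max_atoms:
        prop = model.sample_step(g, rng, temperature=temperature)
        if is_terminal(prop, model, g.n_atoms > 0):
            break
        g = apply_proposal(g, prop, model.bonds)
    return g


def run_atom_search(
    parent: MolGraph,
    parent_site: int,
    eval_fn,
    model: GeneratorModel,
    n_steps: int,
    rng: np.random.Generator | int | None = None,
    k: int = 5,
    max_fragment_atoms: int = 15,
    c: float = math.sqrt(2),
    temperature: float = 1.0,
    transform: RewardTransform | None = None,
) -> list[ScoredCandidate]:
    """Run ``n_steps`` cycles of the inner search; return scored molecules.

    Every completed fragment is attached to ``parent`` at ``parent_site``
    (fragment attachment atom = its first generated atom) and scored with
    ``eval_fn``; results are deduplicated by canonical SMILES, keeping the
    first occurrence.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if free_valence(parent, parent_site) < 1:
        raise ValenceError(
            f"parent atom {parent_site} has no free valence to accept a fragment")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    squash = transform or RewardTransform.for_score(eval_fn)

    root = AtomSearchNode(MolGraph(vocab=parent.vocab))
    results: dict[str, ScoredCandidate] = {}
    reward_cache: dict[str, float] = {}

    def score_fragment(frag: MolGraph) -> float:
        """Attach, evaluate, record; reward for backpropagation."""
        if frag.n_atoms == 0:
            return squash(eval_fn(parent))  # generator declined to grow
        key = frag.canonical()
        if key in reward_cache:
            return reward_cache[key]
        if free_valence(frag, 0) < 1:
            reward_cache[key] = -1.0  # first atom saturated: unattachable
            return -1.0
        mol = attach_fragment(parent, frag, AttachmentSite(parent_site, 0))
        raw = eval_fn(mol)
        smiles = mol.canonical()
        if smiles not in results:
            results[smiles] = ScoredCandidate(mol, smiles, raw, key, frag.n_atoms)
        reward = squash(raw)
        reward_cache[key] = reward
        return reward

    for _ in range(n_steps):
        # selection
        node = root
        while node.children:
            node = max(node.children,
                       key=lambda ch: ucb1(ch.mean, ch.visits, node.visits, c))
        # expansion
        if not node.terminal and node.partial.n_atoms < max_fragment_atoms:
            for prop in model.top_proposals(node.partial, k=k,
                                            temperature=temperature):
                if is_terminal(prop, model, node.partial.n_atoms > 0):
                    child = AtomSearchNode(node.partial, parent=node,
                                           terminal=True, prior=prop.prob)
                else:
                    child = AtomSearchNode(apply_proposal(node.partial, prop,
                                                          model.bonds),
                                           parent=node, prior=prop.prob)
                node.children.append(child)
        elif not node.terminal:
            node.terminal = True  # size cap reached

        # simulation
        if node.children:
            start = max(node.children, key=lambda ch: ch.prior)
        else:
            start = node
        if start.terminal:
            fragment = start.partial
        else:
            fragment = _rollout(start.partial, model, rng,
                                max_fragment_atoms, temperature)
        reward = score_fragment(fragment)

        # backpropagation
        walk = start
        while walk is not None:
            walk.value_sum += reward
            walk.visits += 1
            walk = walk.parent

    out = list(results.values())
    out.sort(key=lambda sc: -sc.raw)
    return out
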