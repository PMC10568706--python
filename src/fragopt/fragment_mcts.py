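"""Outer fragment-wise Monte Carlo tree search over molecules.

The root of the tree is the starting molecule.  One cycle is:

1. *Selection* — descend from the root by the UCB1 score
   ``x̄ + c·sqrt(2·ln(n_p)/n)`` (unvisited children first) to a leaf.
2. *Expansion* — children are molecules reachable by one fragment edit:
   every single-bond cut that disconnects the molecule contributes the
   larger component (fragment removal), and the inner atom-wise search
   grows fragments onto a randomly chosen free-valence atom (fragment
   addition).  Addition children pass an ε-greedy filter: with
   probability 1−ε the top-m by raw score are kept, otherwise m random.
3. *Evaluation* — each new child molecule is scored by the evaluation
   function directly; there is no rollout, because an arbitrary starting
   molecule has no natural terminal state.
4. *Backpropagation* — the MAXIMUM squashed child reward is added along
   the path from the root to the expanded node, and every node on the
   path gains one visit.

Rewards are squashed into [−1, 1]: linearly (2r − 1) for scorers with a
declared [0, 1] range, through tanh(r/s) for unbounded scorers.

Every molecule the search ever adds is emitted; because all edits go
through valence-checked graph primitives, emitted molecules are valid by
construction (validity ≡ 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem_graph import MolGraph, free_valence, enumerate_removals, parse_smiles
from .gcn_model import GeneratorModel
from .scoring import ScoreFunction, is_failed, tanimoto_ecfp4

log = logging.getLogger(__name__)

__all__ = [
    "SearchNode",
    "RewardTransform",
    "OptimizeConfig",
    "ucb1",
    "optimize",
    "rank_and_report",
]


def ucb1(mean_reward: float, visits: int, parent_visits: int,
         c: float = math.sqrt(2)) -> float:
    """Upper-confidence-bound score; unvisited nodes score +inf."""
    if visits < 0 or parent_visits < 0:
        raise ValueError("visit counts must be non-negative")
    if visits == 0:
        return math.inf
    if parent_visits == 0:
        return mean_reward
    return mean_reward + c * math.sqrt(2.0 * math.log(parent_visits) / visits)


@dataclass(frozen=True)
class RewardTransform:
    """Strictly monotone map of raw scores into [−1, 1].

    ``linear`` maps a known score range [lo, hi] onto the full interval;
    ``tanh`` squashes unbounded scores as tanh(raw / scale).  The failed-
    constraint sentinel (−inf) maps to −1 under both.
    """

    kind: str = "linear"          # "linear" | "tanh"
    lo: float = 0.0
    hi: float = 1.0
    scale: float = 10.0

    def __call__(self, raw: float) -> float:
        if math.isnan(raw):
            raise ValueError("reward must not be NaN")
        if is_failed(raw):
            return -1.0
        if self.kind == "linear":
            x = 2.0 * (raw - self.lo) / (self.hi - self.lo) - 1.0
            return min(1.0, max(-1.0, x))
        if self.kind == "tanh":
            return math.tanh(raw / self.scale)
        raise ValueError(f"unknown transform kind {self.kind!r}")

    @classmethod
    def for_score(cls, score: ScoreFunction | None) -> "RewardTransform":
        rng = getattr(score, "declared_range", None)
        if rng is not None:
            return cls("linear", lo=rng[0], hi=rng[1])
        return cls("tanh")


@dataclass
class SearchNode:
    mol: MolGraph
    value_sum: float = 0.0
    visits: int = 0
    parent: "SearchNode | None" = None
    children: list["SearchNode"] = field(default_factory=list)
    raw_score: float = float("nan")
    expanded: bool = False

    @property
    def mean(self) -> float:
        return self.value_sum / self.visits if self.visits else 0.0


@dataclass
class OptimizeConfig:
    """Knobs of the outer search (defaults mirror the reference protocol)."""

    exploration_c: float = math.sqrt(2)
    epsilon: float = 0.2          # ε-greedy addition filter
    m_additions: int = 5          # addition children kept per expansion
    k_expansion: int = 5          # inner-search expansion breadth
    max_fragment_atoms: int = 15  # hard cap on generated fragment size
    temperature: float = 1.0
    protected_smarts: str | None = None  # substructure never removed
    transform: RewardTransform | None = None


def _select_leaf(root: SearchNode, c: float) -> SearchNode:
    node = root
    while node.children:
        node = max(node.children,
                   key=lambda ch: ucb1(ch.mean, ch.visits, node.visits, c))
    return node


def _backpropagate(node: SearchNode, reward: float) -> None:
    while node is not None:
        node.value_sum += reward
        node.visits += 1
        node = node.parent


def _keeps_protected(mol: MolGraph, pattern) -> bool:
    return pattern is None or mol.to_rdkit().HasSubstructMatch(pattern)


def optimize(
    seed: MolGraph | str,
    eval_fn: ScoreFunction,
    model: GeneratorModel,
    fragment_steps: int,
    atom_steps: int,
    cfg: OptimizeConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[tuple[str, float]]:
    """Optimize a starting molecule; return all generated molecules ranked.

    Returns (canonical SMILES, raw score) pairs sorted by score descending,
    deduplicated, excluding the seed itself.
    """
    from .atom_mcts import run_atom_search  # deferred: avoids an import cycle
    from rdkit import Chem

    if isinstance(seed, str):
        seed = parse_smiles(seed, model.vocab)
    if fragment_steps < 1:
        raise ValueError("fragment_steps must be >= 1")
    cfg = cfg or OptimizeConfig()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    squash = cfg.transform or RewardTransform.for_score(eval_fn)
    pattern = (Chem.MolFromSmarts(cfg.protected_smarts)
               if cfg.protected_smarts else None)

    root = SearchNode(seed)
    seen: dict[str, float] = {}
    seed_key = seed.canonical()
    tree_size = 1

    for cycle in range(1, fragment_steps + 1):
        node = _select_leaf(root, cfg.exploration_c)
        new_children: list[SearchNode] = []
        if not node.expanded:
            node.expanded = True
            # (a) fragment removals
            for child_mol in enumerate_removals(node.mol):
                if not _keeps_protected(child_mol, pattern):
                    continue
                raw = eval_fn(child_mol)
                new_children.append(SearchNode(child_mol, parent=node,
                                               raw_score=raw))
            # (b) fragment additions via the inner atom-wise search
            sites = [i for i in range(node.mol.n_atoms)
                     if free_valence(node.mol, i) >= 1]
            if sites:
                site = int(rng.choice(sites))
                scored = run_atom_search(
                    node.mol, site, eval_fn, model, atom_steps, rng,
                    k=cfg.k_expansion, max_fragment_atoms=cfg.max_fragment_atoms,
                    c=cfg.exploration_c, temperature=cfg.temperature,
                    transform=squash)
                scored.sort(key=lambda sc: -sc.raw)
                if rng.random() < cfg.epsilon and len(scored) > cfg.m_additions:
                    picks = rng.choice(len(scored), size=cfg.m_additions,
                                       replace=False)
                    kept = [scored[i] for i in picks]
                else:
                    kept = scored[:cfg.m_additions]
                for cand in kept:
                    new_children.append(SearchNode(
                        cand.mol, parent=node, raw_score=cand.raw))
            if not new_children and node is root:
                raise ValueError(
                    "no expandable edit for the seed molecule "
                    "(no removable fragment and no free-valence site)")
            node.children.extend(new_children)
        if new_children:
            for child in new_children:
                key = child.mol.canonical()
                if key != seed_key:
                    prev = seen.get(key)
                    if prev is None or child.raw_score > prev:
                        seen[key] = child.raw_score
            reward = max(squash(ch.raw_score) for ch in new_children)
        else:
            # terminal or exhausted node: reuse its own evaluation
            raw = node.raw_score
            if math.isnan(raw):
                raw = eval_fn(node.mol)
            reward = squash(raw)
        _backpropagate(node, reward)
        tree_size += len(new_children)
        if seen:
            log.info("cycle %d/%d: best %.4f over %d molecules, tree size %d",
                     cycle, fragment_steps, max(seen.values()), len(seen),
                     tree_size)

    ranked = sorted(seen.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked


def rank_and_report(results: list[tuple[str, float]], seed: MolGraph | str,
                    top_k: int = 50) -> pd.DataFrame:
    """Top-k table with raw scores and ECFP4 Tanimoto similarity to the seed."""
    if not results:
        raise ValueError("no results to report")
    seed_smiles = seed if isinstance(seed, str) else seed.canonical()
    rows = [
        {"rank": i + 1, "smiles": s, "score": v,
         "similarity": tanimoto_ecfp4(s, seed_smiles)}
        for i, (s, v) in enumerate(results[:top_k])
    ]
    return pd.DataFrame(rows)
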