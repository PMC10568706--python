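"""Evaluation functions and generation-quality metrics.

All scorers are pure functions of the molecule (deterministic, no hidden
state).  Built-ins:

* ``qed`` — quantitative estimate of drug-likeness, in [0, 1].
* ``plogp`` — penalized logP: Crippen logP minus the synthetic-
  accessibility score minus a large-ring penalty (number of atoms beyond
  six in the largest ring), unnormalised.
* similarity-constrained wrappers that return a ``-inf`` sentinel when the
  candidate drifts below a Tanimoto/ECFP4 threshold from the seed, so
  constrained candidates are never selected.

Custom scorers plug in as any callable mapping a canonical SMILES string
to a finite real; :func:`get_score_function` loads ``custom:<path>`` from
a Python file exposing ``score(smiles) -> float``.
"""

from __future__ import annotations

import functools
import importlib.util
import math
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, DataStructs, QED, RDConfig

sys.path.append(str(Path(RDConfig.RDContribDir) / "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib, shipped with the rdkit package)

from .chem_graph import MolGraph

__all__ = [
    "ScoreFunction",
    "qed_score",
    "penalized_logp",
    "tanimoto_ecfp4",
    "similarity_constrained_score",
    "generation_metrics",
    "get_score_function",
    "FAILED_CONSTRAINT",
]

#: Sentinel reward for molecules violating a hard constraint.
FAILED_CONSTRAINT = float("-inf")


@dataclass(frozen=True)
class ScoreFunction:
    """A named molecular scorer with an optional declared value range.

    The declared range decides the default reward squashing in the search:
    scorers with range [0, 1] map linearly onto [-1, 1]; unbounded scorers
    go through a scaled tanh.
    """

    name: str
    fn: Callable[[str], float]
    declared_range: tuple[float, float] | None = None

    def __call__(self, mol: "MolGraph | str") -> float:
        smiles = mol if isinstance(mol, str) else mol.canonical()
        return self.fn(smiles)


@functools.lru_cache(maxsize=200_000)
def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unscorable SMILES {smiles!r}")
    return mol


@functools.lru_cache(maxsize=200_000)
def _qed(smiles: str) -> float:
    return float(QED.qed(_mol(smiles)))


def qed_score(mol: MolGraph | str) -> float:
    """Quantitative estimate of drug-likeness, in [0, 1]."""
    return _qed(mol if isinstance(mol, str) else mol.canonical())


def _largest_ring_penalty(mol: Chem.Mol) -> float:
    sizes = [len(r) for r in mol.GetRingInfo().AtomRings()]
    return float(max(0, max(sizes, default=0) - 6))


@functools.lru_cache(maxsize=200_000)
def _plogp(smiles: str) -> float:
    mol = _mol(smiles)
    return (float(Crippen.MolLogP(mol))
            - float(sascorer.calculateScore(mol))
            - _largest_ring_penalty(mol))


def penalized_logp(mol: MolGraph | str) -> float:
    """logP − SA score − (largest ring size − 6, floored at 0)."""
    return _plogp(mol if isinstance(mol, str) else mol.canonical())


@functools.lru_cache(maxsize=200_000)
def _ecfp4(smiles: str):
    return AllChem.GetMorganFingerprintAsBitVect(_mol(smiles), radius=2,
                                                 nBits=2048)


def tanimoto_ecfp4(a: MolGraph | str, b: MolGraph | str) -> float:
    """Tanimoto similarity of 2048-bit radius-2 circular fingerprints."""
    sa = a if isinstance(a, str) else a.canonical()
    sb = b if isinstance(b, str) else b.canonical()
    return float(DataStructs.TanimotoSimilarity(_ecfp4(sa), _ecfp4(sb)))


def similarity_constrained_score(
    mol: MolGraph | str, seed: MolGraph | str, delta: float,
    base: Callable[[MolGraph | str], float],
) -> float:
    """``base(mol)`` if Tanimoto(mol, seed) >= delta, else ``-inf``."""
    if not 0.0 <= delta <= 1.0:
        raise ValueError(f"delta must be in [0, 1], got {delta}")
    if tanimoto_ecfp4(mol, seed) >= delta:
        return base(mol)
    return FAILED_CONSTRAINT


def generation_metrics(generated: list[str], training_corpus: list[str],
                       seed: str | None = None) -> dict:
    """Validity, novelty, uniqueness and the per-molecule seed similarity.

    ``generated`` may contain arbitrary strings; validity is the fraction
    that parse.  Novelty and uniqueness are computed over the valid set,
    by canonical SMILES.
    """
    if not generated:
        raise ValueError("generated list is empty")
    valid = []
    for s in generated:
        mol = Chem.MolFromSmiles(s)
        if mol is not None:
            valid.append(Chem.MolToSmiles(mol))
    corpus = set()
    for s in training_corpus:
        mol = Chem.MolFromSmiles(s)
        if mol is not None:
            corpus.add(Chem.MolToSmiles(mol))
    out = {
        "validity": len(valid) / len(generated),
        "novelty": (sum(1 for s in valid if s not in corpus) / len(valid)
                    if valid else 0.0),
        "uniqueness": (len(set(valid)) / len(valid) if valid else 0.0),
    }
    if seed is not None:
        out["similarity"] = [tanimoto_ecfp4(s, seed) for s in valid]
    return out


def _load_custom(path: str) -> Callable[[str], float]:
    spec = importlib.util.spec_from_file_location("fragopt_custom_score", path)
    if spec is None or spec.loader is None:
        raise ValueError(f"cannot load custom scorer from {path!r}")
    module = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(module)
    if not hasattr(module, "score"):
        raise ValueError(f"{path!r} must define score(smiles) -> float")
    return module.score


def get_score_function(name: str, seed: str | None = None,
                       delta: float = 0.4) -> ScoreFunction:
    """Resolve an evaluation function by name.

    ``qed``, ``plogp``, ``plogp_sim`` (similarity-constrained penalized
    logP around ``seed``), or ``custom:<path.py>``.
    """
    if name == "qed":
        return ScoreFunction("qed", _qed, (0.0, 1.0))
    if name == "plogp":
        return ScoreFunction("plogp", _plogp, None)
    if name == "plogp_sim":
        if seed is None:
            raise ValueError("plogp_sim requires a seed molecule")
        fn = functools.partial(similarity_constrained_score,
                               seed=seed, delta=delta, base=_plogp)
        return ScoreFunction(f"plogp_sim(delta={delta})", fn, None)
    if name.startswith("custom:"):
        fn = _load_custom(name.split(":", 1)[1])
        return ScoreFunction(name, lambda s: float(fn(s)), None)
    raise ValueError(f"unknown score function {name!r}")


def is_failed(value: float) -> bool:
    return math.isinf(value) and value < 0
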